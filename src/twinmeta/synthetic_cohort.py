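"""Fully synthetic monozygotic-twin metagenome cohort generator.

Emulates the statistical structure the downstream analyses assume: a cohort
of MZ twin pairs sampled at up to two time points, with

* twin-correlated species composition (a shared pair-level lognormal latent
  component mixed into each subject's species profile),
* co-abundance groups of species (a shared group latent), so that
  taxon-taxon co-occurrence is present for the 'associated' classification,
* per-subject strain barcodes over each species' marker genes, with tunable
  twin divergence and within-subject temporal divergence,
* marker RPK values tied mechanistically to species abundance
  (RPK = depth x relative abundance x barcode presence x lognormal noise),
* KEGG-module abundances derived from species abundances through a
  genome-carriage matrix, and
* clinical metadata (BMI, fasting glucose/insulin, HOMA, blood pressure,
  triglycerides, hsCRP, age, sex, smoking) with optional planted
  microbe-phenotype effects applied on the arcsin-sqrt scale, so the
  association stage's model is correctly specified under the generator.

Identical configuration and seed give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .profile_io import (
    AbundanceTable,
    CarriageMatrix,
    FunctionTable,
    MarkerProfileSet,
    MetadataTable,
)

__all__ = [
    "PlantedEffect",
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "derive_module_abundances",
    "generate_strain_barcodes",
    "compute_homa",
    "species_name",
    "module_name",
    "unrelated_divergence",
]

#: standard deviation of the subject-level species log-abundance latent
_SUBJECT_LOG_SD = 1.0
#: standard deviation of the per-species baseline log-mean spread
_BASELINE_LOG_SD = 1.5
#: centre of the planted-feature transformed abundance (arcsin-sqrt scale)
_PLANTED_CENTRE = 0.35

_PHYLA = ("Bacteroidetes", "Firmicutes", "Actinobacteria", "Proteobacteria", "Verrucomicrobia")


class PlantedEffect(NamedTuple):
    """A ground-truth microbe-phenotype association planted in the cohort."""

    variable: str  # clinical variable name, e.g. "bmi"
    feature: str  # species short name or module identifier
    sign: int  # +1 or -1
    size: float  # slope on the arcsin-sqrt scale per SD of the variable


def species_name(index: int) -> str:
    """Short name of the ``index``-th synthetic species (0-based)."""
    return f"Synthsp_{index + 1:03d}"


def module_name(index: int) -> str:
    """Identifier of the ``index``-th synthetic KEGG-style module (0-based)."""
    return f"M{index + 1:05d}"


def unrelated_divergence(presence_prob: float) -> float:
    """Expected barcode discordance between two unrelated strains.

    Two independent Bernoulli(p) presence patterns differ at a fraction
    2 p (1 - p) of markers; this is the ceiling for twin divergence under the
    marginal-preserving twin model.
    """
    return 2.0 * presence_prob * (1.0 - presence_prob)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one synthetic twin cohort.

    The defaults reproduce the study layout the analyses target: 10 MZ twin
    pairs, up to two time points, four samples missing, i.e. 36 stool
    metagenomes.
    """

    n_pairs: int = 10
    n_timepoints: int = 2
    n_dropped_samples: int = 4
    n_species: int = 30
    n_modules: int = 20
    n_markers_per_species: int = 50
    twin_species_correlation: float = 0.5
    strain_twin_divergence: float = 0.3
    strain_self_divergence: float = 0.02
    marker_presence_prob: float = 0.8
    depth_factor: float = 1000.0
    cooccurrence_group_size: int = 3
    cooccurrence_strength: float = 0.6
    planted_effects: tuple[PlantedEffect, ...] = ()
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        def fail(name: str, why: str) -> None:
            raise ValueError(f"{name}: {why} (got {getattr(self, name)!r})")

        if self.n_pairs < 2:
            fail("n_pairs", "need at least 2 twin pairs")
        if self.n_timepoints not in (1, 2):
            fail("n_timepoints", "must be 1 or 2")
        max_drop = 2 * self.n_pairs * self.n_timepoints - 3
        if not 0 <= self.n_dropped_samples < max_drop:
            fail("n_dropped_samples", f"must be in [0, {max_drop})")
        for name in ("n_species", "n_modules", "n_markers_per_species"):
            if getattr(self, name) < 1:
                fail(name, "must be >= 1")
        for name in (
            "twin_species_correlation",
            "strain_twin_divergence",
            "strain_self_divergence",
            "marker_presence_prob",
            "cooccurrence_strength",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                fail(name, "must lie in [0, 1]")
        if self.depth_factor <= 0:
            fail("depth_factor", "must be positive")
        if self.cooccurrence_group_size < 1:
            fail("cooccurrence_group_size", "must be >= 1")
        if self.noise_sd < 0:
            fail("noise_sd", "must be non-negative")
        object.__setattr__(
            self, "planted_effects", tuple(PlantedEffect(*e) for e in self.planted_effects)
        )
        for eff in self.planted_effects:
            if eff.sign not in (-1, 1):
                fail("planted_effects", f"effect sign must be +1/-1, got {eff.sign}")
            if eff.size < 0:
                fail("planted_effects", "effect size must be non-negative")


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream validation."""

    planted_effects: tuple[PlantedEffect, ...]
    #: species -> sample_id -> binary marker-presence vector
    barcodes: dict[str, dict[str, np.ndarray]]
    #: subject_id -> pair_id
    pair_of_subject: dict[str, str]
    #: species short name -> co-occurrence group index
    cooccurrence_group: dict[str, int]


@dataclass
class SyntheticCohort:
    abundance: AbundanceTable
    functions: FunctionTable
    markers: MarkerProfileSet
    metadata: MetadataTable
    carriage: CarriageMatrix
    truth: GroundTruth

    @property
    def sample_ids(self) -> list[str]:
        return self.abundance.sample_ids


def compute_homa(fbi, fbs):
    """HOMA insulin-resistance index: (fasting insulin x fasting glucose) / 405.

    Insulin in uU/mL, glucose in mg/dL; dimensionless result.
    """
    fbi = np.asarray(fbi, dtype=float)
    fbs = np.asarray(fbs, dtype=float)
    if (fbi < 0).any() or (fbs < 0).any():
        raise ValueError("HOMA inputs must be non-negative")
    out = fbi * fbs / 405.0
    return float(out) if out.ndim == 0 else out


def generate_strain_barcodes(
    n_markers: int,
    divergence: float,
    seed: int | np.random.Generator,
    presence_prob: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a pair of strain barcodes at a given expected divergence.

    ``barcode_a`` is Bernoulli(``presence_prob``) per marker; ``barcode_b`` is
    derived from it by flipping each marker's presence independently with
    probability ``divergence``, so the expected Hamming distance is
    ``divergence * n_markers``.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must lie in [0, 1], got {divergence}")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = (rng.random(n_markers) < presence_prob).astype(np.int8)
    flips = rng.random(n_markers) < divergence
    b = np.where(flips, 1 - a, a).astype(np.int8)
    return a, b


def _twin_barcodes_symmetric(
    ancestor: np.ndarray, divergence: float, presence_prob: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Derive two twin barcodes with Bernoulli(p) marginals for both twins.

    Each twin copies the ancestral marker with probability rho and redraws it
    fresh from Bernoulli(p) otherwise; rho is chosen so the expected twin
    discordance equals ``divergence`` (capped at the unrelated ceiling
    2 p (1 - p), where the twins become independent).
    """
    ceiling = unrelated_divergence(presence_prob)
    if ceiling <= 0:
        return ancestor.copy(), ancestor.copy()
    rho = math.sqrt(max(0.0, 1.0 - divergence / ceiling))
    out = []
    for _ in range(2):
        copy = rng.random(ancestor.size) < rho
        fresh = (rng.random(ancestor.size) < presence_prob).astype(np.int8)
        out.append(np.where(copy, ancestor, fresh).astype(np.int8))
    return out[0], out[1]


def _flip(barcode: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    flips = rng.random(barcode.size) < p
    return np.where(flips, 1 - barcode, barcode).astype(np.int8)


def _species_lineage(index: int) -> str:
    phylum = _PHYLA[index % len(_PHYLA)]
    return (
        f"k__Bacteria|p__{phylum}|c__{phylum}_c|o__{phylum}_o"
        f"|f__Family_{index // 4 + 1:02d}|g__Genus_{index // 2 + 1:02d}|s__{species_name(index)}"
    )


def _sample_frame(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample layout after dropping: one row per retained (subject, timepoint)."""
    rows = []
    for p in range(config.n_pairs):
        pair = f"pair{p + 1:02d}"
        for letter in "ab":
            subject = f"{pair}{letter}"
            for tp in range(1, config.n_timepoints + 1):
                rows.append((f"{subject}_t{tp}", subject, pair, tp))
    frame = pd.DataFrame(rows, columns=["sample_id", "subject_id", "pair_id", "timepoint"])
    if config.n_dropped_samples:
        # emulate incomplete sampling: whole pairs lose their later time point
        # first (as in cohorts where some pairs were sampled only once)
        pair_order = list(rng.permutation(sorted(frame["pair_id"].unique())))
        candidates: list[str] = []
        for tp in range(config.n_timepoints, 0, -1):
            for pair in pair_order:
                sel = frame[(frame["pair_id"] == pair) & (frame["timepoint"] == tp)]
                candidates.extend(sel["sample_id"])
        drop = set(candidates[: config.n_dropped_samples])
        frame = frame[~frame["sample_id"].isin(drop)]
    return frame.reset_index(drop=True)


def _clip_lognormal(rng, mean: float, sigma: float, size, lo: float, hi: float) -> np.ndarray:
    return np.clip(rng.lognormal(math.log(mean), sigma, size), lo, hi)


def _generate_metadata(config: CohortConfig, frame: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    pairs = sorted(frame["pair_id"].unique())
    pair_age = {p: int(rng.integers(30, 49)) for p in pairs}
    pair_sex = {p: rng.choice(["female", "male"]) for p in pairs}
    pair_smoking = {p: rng.choice(["never", "former", "current"], p=[0.6, 0.2, 0.2]) for p in pairs}
    pair_bmi_base = {p: rng.uniform(20.0, 26.0) for p in pairs}
    subjects = sorted(frame["subject_id"].unique())
    subj_bmi = {
        s: float(np.clip(pair_bmi_base[s[:-1]] + rng.normal(0.0, 1.5), 18.0, 28.0))
        for s in subjects
    }
    n = len(frame)
    df = frame.copy()
    df["age"] = [pair_age[p] for p in df["pair_id"]]
    df["sex"] = [pair_sex[p] for p in df["pair_id"]]
    df["smoking"] = [pair_smoking[p] for p in df["pair_id"]]
    df["bmi"] = np.clip(
        np.array([subj_bmi[s] for s in df["subject_id"]]) + rng.normal(0.0, 0.5, n), 18.0, 28.0
    )
    df["fbs"] = np.clip(rng.normal(88.0, 9.0, n), 70.0, 118.0)
    df["fbi"] = _clip_lognormal(rng, 8.0, 0.4, n, 2.0, 25.0)
    df["homa"] = compute_homa(df["fbi"].to_numpy(), df["fbs"].to_numpy())
    df["systolic_bp"] = np.clip(rng.normal(115.0, 10.0, n), 95.0, 145.0)
    df["diastolic_bp"] = np.clip(rng.normal(75.0, 8.0, n), 55.0, 95.0)
    df["triglycerides"] = _clip_lognormal(rng, 110.0, 0.35, n, 45.0, 260.0)
    df["hscrp"] = _clip_lognormal(rng, 0.8, 0.7, n, 0.05, 8.0)
    return df


def _species_abundances(
    config: CohortConfig, frame: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, int]]:
    """Sample x species proportions with pair- and co-occurrence structure."""
    n_sp = config.n_species
    pairs = sorted(frame["pair_id"].unique())
    subjects = sorted(frame["subject_id"].unique())
    pair_idx = {p: i for i, p in enumerate(pairs)}
    subj_idx = {s: i for i, s in enumerate(subjects)}
    w = config.twin_species_correlation
    groups = {species_name(i): i // config.cooccurrence_group_size for i in range(n_sp)}
    n_groups = max(groups.values()) + 1

    def structured_latent(n_cols: int) -> np.ndarray:
        """Subject x n_cols latent with twin (pair-level) correlation w."""
        z_pair = rng.normal(size=(len(pairs), n_cols))
        z_subj = rng.normal(size=(len(subjects), n_cols))
        lat = np.empty((len(subjects), n_cols))
        for s, i in subj_idx.items():
            lat[i] = math.sqrt(w) * z_pair[pair_idx[s[:-1]]] + math.sqrt(1.0 - w) * z_subj[i]
        return lat

    own = structured_latent(n_sp)
    grp = structured_latent(n_groups)
    c = config.cooccurrence_strength
    latent = np.empty_like(own)
    for j in range(n_sp):
        latent[:, j] = math.sqrt(c) * grp[:, groups[species_name(j)]] + math.sqrt(1.0 - c) * own[:, j]

    mu = rng.normal(0.0, _BASELINE_LOG_SD, n_sp)
    eps = rng.normal(0.0, config.noise_sd, size=(len(frame), n_sp))
    rows = np.array([subj_idx[s] for s in frame["subject_id"]])
    log_a = mu[None, :] + _SUBJECT_LOG_SD * latent[rows] + eps
    a = np.exp(log_a)
    a /= a.sum(axis=1, keepdims=True)
    return a, groups


def _apply_planted_effects(
    values: np.ndarray,
    feature_names: Sequence[str],
    effects: Sequence[PlantedEffect],
    metadata: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overwrite planted feature columns with a monotone clinical-variable shift.

    The planted feature's arcsin-sqrt-transformed abundance is
    centre + sign * size * z(variable) + pair intercept + residual noise,
    back-transformed and renormalised, so a linear mixed model on the
    transformed scale is (approximately) correctly specified.
    """
    applicable = [e for e in effects if e.feature in feature_names]
    if not applicable:
        return values
    out = values.copy()
    name_idx = {f: j for j, f in enumerate(feature_names)}
    pairs = sorted(metadata["pair_id"].unique())
    for eff in applicable:
        v = metadata[eff.variable].to_numpy(dtype=float)
        z = (v - v.mean()) / (v.std() or 1.0)
        pair_re = {p: rng.normal(0.0, config.noise_sd) for p in pairs}
        re = np.array([pair_re[p] for p in metadata["pair_id"]])
        resid = rng.normal(0.0, config.noise_sd, v.size)
        t = _PLANTED_CENTRE + eff.sign * eff.size * z + re + resid
        t = np.clip(t, 0.02, math.pi / 2 - 0.02)
        out[:, name_idx[eff.feature]] = np.sin(t) ** 2
    out /= out.sum(axis=1, keepdims=True)
    return out


def derive_module_abundances(
    species: AbundanceTable,
    carriage: CarriageMatrix,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> FunctionTable:
    """Generate KEGG-module abundances from species abundances via carriage.

    Pre-noise module mass per sample is ``sum_s abundance(s) * carriage(s, m)``;
    multiplicative lognormal noise is applied and rows renormalised to sum 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    short = [s for s in species.feature_names]
    c = carriage.data.reindex(index=short).fillna(0.0)
    if not np.any(c.to_numpy() > 0):
        raise ValueError("carriage matrix is all zero: no module mass to normalise")
    mass = species.data.to_numpy() @ c.to_numpy()
    if noise_sd > 0:
        mass = mass * rng.lognormal(0.0, noise_sd, size=mass.shape)
    sums = mass.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        bad = np.asarray(species.sample_ids)[(sums <= 0).ravel()]
        raise ValueError(f"zero module mass for samples {list(bad)}")
    return FunctionTable(data=pd.DataFrame(mass / sums, index=species.data.index, columns=carriage.modules))


def _generate_carriage(config: CohortConfig, rng: np.random.Generator) -> CarriageMatrix:
    carriers = rng.random((config.n_species, config.n_modules)) < 0.25
    for j in range(config.n_modules):  # every module needs at least one carrier
        if not carriers[:, j].any():
            carriers[int(rng.integers(config.n_species)), j] = True
    df = pd.DataFrame(
        carriers.astype(float),
        index=[species_name(i) for i in range(config.n_species)],
        columns=[module_name(j) for j in range(config.n_modules)],
    )
    return CarriageMatrix(data=df)


def _generate_markers(
    config: CohortConfig,
    frame: pd.DataFrame,
    abundance: np.ndarray,
    rng: np.random.Generator,
) -> tuple[MarkerProfileSet, dict[str, dict[str, np.ndarray]]]:
    m = config.n_markers_per_species
    marker_ids = [f"marker_{k + 1:04d}" for k in range(m)]
    pairs = sorted(frame["pair_id"].unique())
    tables: dict[str, pd.DataFrame] = {}
    truth: dict[str, dict[str, np.ndarray]] = {}
    for j in range(config.n_species):
        sp = species_name(j)
        subj_bc: dict[tuple[str, int], np.ndarray] = {}
        for pair in pairs:
            ancestor = (rng.random(m) < config.marker_presence_prob).astype(np.int8)
            bc_a, bc_b = _twin_barcodes_symmetric(
                ancestor, config.strain_twin_divergence, config.marker_presence_prob, rng
            )
            for subject, bc in ((f"{pair}a", bc_a), (f"{pair}b", bc_b)):
                subj_bc[(subject, 1)] = bc
                subj_bc[(subject, 2)] = _flip(bc, config.strain_self_divergence, rng)
        rpk = np.empty((len(frame), m))
        sample_bc: dict[str, np.ndarray] = {}
        for i, row in enumerate(frame.itertuples(index=False)):
            bc = subj_bc[(row.subject_id, row.timepoint)]
            noise = rng.lognormal(0.0, config.noise_sd, m) if config.noise_sd > 0 else 1.0
            rpk[i] = config.depth_factor * abundance[i, j] * bc * noise
            sample_bc[row.sample_id] = bc
        tables[sp] = pd.DataFrame(rpk, index=list(frame["sample_id"]), columns=marker_ids)
        truth[sp] = sample_bc
    return MarkerProfileSet(species_tables=tables), truth


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one synthetic twin cohort; identical seed, identical output."""
    ss = np.random.SeedSequence(config.seed)
    r_drop, r_meta, r_ab, r_planted, r_strain, r_carriage, r_mod = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )
    frame = _sample_frame(config, r_drop)
    meta_df = _generate_metadata(config, frame, r_meta)

    species_names = [species_name(i) for i in range(config.n_species)]
    module_names = [module_name(j) for j in range(config.n_modules)]
    for eff in config.planted_effects:
        if eff.variable not in meta_df.columns:
            raise ValueError(f"planted_effects: unknown clinical variable {eff.variable!r}")
        if eff.feature not in species_names and eff.feature not in module_names:
            raise ValueError(f"planted_effects: unknown feature {eff.feature!r}")

    abundance, groups = _species_abundances(config, frame, r_ab)
    abundance = _apply_planted_effects(
        abundance, species_names, config.planted_effects, meta_df, config, r_planted
    )
    abundance_table = AbundanceTable(
        data=pd.DataFrame(
            abundance,
            index=list(frame["sample_id"]),
            columns=[_species_lineage(i) for i in range(config.n_species)],
        ),
        rank="species",
    )

    markers, barcode_truth = _generate_markers(config, frame, abundance, r_strain)
    carriage = _generate_carriage(config, r_carriage)
    functions = derive_module_abundances(abundance_table, carriage, config.noise_sd, r_mod)
    module_effects = [e for e in config.planted_effects if e.feature in module_names]
    if module_effects:
        shifted = _apply_planted_effects(
            functions.data.to_numpy(), module_names, module_effects, meta_df, config, r_planted
        )
        functions = FunctionTable(
            data=pd.DataFrame(shifted, index=functions.data.index, columns=module_names)
        )

    metadata = MetadataTable(data=meta_df)
    truth = GroundTruth(
        planted_effects=config.planted_effects,
        barcodes=barcode_truth,
        pair_of_subject={s: s[:-1] for s in frame["subject_id"].unique()},
        cooccurrence_group=groups,
    )
    return SyntheticCohort(
        abundance=abundance_table,
        functions=functions,
        markers=markers,
        metadata=metadata,
        carriage=carriage,
        truth=truth,
    )
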