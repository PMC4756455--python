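"""End-to-end recovery studies on synthetic cohorts, plus reference oracles.

This module answers "does the pipeline recover what the generator planted?"
with small, seeded simulation studies:

* association: planted microbe-phenotype effect recovered with the right
  sign at q < 0.2, and the false-call fraction under the global null;
* strains: twin-vs-self contrast power when twin strains diverge and self
  strains are stable, and the twin-vs-unrelated null when twin strain (and
  species) structure is removed;
* taxon-function: encoded/associated classification recovery under
  low-noise module generation from a known carriage matrix;
* community: the self < twin < unrelated ordering of mean Bray-Curtis
  distances.

It also carries deliberately naive reference implementations (textbook
formula, double loop, step-up by hand) of Bray-Curtis, Spearman and
Benjamini-Hochberg, used to cross-check the library-backed fast paths.
The study problem sizes are chosen to resolve the qualitative patterns in
seconds to a couple of minutes on one CPU; docs/methods.md records them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import association, community_analysis, strain_fingerprint, taxon_function
from .profile_io import species_short_name
from .synthetic_cohort import (
    CohortConfig,
    PlantedEffect,
    generate_cohort,
    species_name,
    unrelated_divergence,
)

__all__ = [
    "bray_curtis_reference",
    "spearman_rho_reference",
    "fdr_bh_reference",
    "oracle_deviations",
    "association_recovery",
    "strain_contrast_study",
    "classification_recovery",
    "community_ordering",
    "correlation_cardinality",
]


# ---------------------------------------------------------------------------
# naive reference implementations (oracles)


def bray_curtis_reference(a, b) -> float:
    """Elementwise-loop Bray-Curtis, straight from the formula."""
    num = 0.0
    den = 0.0
    for ai, bi in zip(a, b):
        num += abs(ai - bi)
        den += ai + bi
    return num / den


def spearman_rho_reference(x, y) -> float:
    """Average-rank transform followed by the textbook Pearson formula."""
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    mx, my = rx.mean(), ry.mean()
    num = float(np.sum((rx - mx) * (ry - my)))
    den = float(np.sqrt(np.sum((rx - mx) ** 2) * np.sum((ry - my) ** 2)))
    return num / den


def fdr_bh_reference(p) -> np.ndarray:
    """Benjamini-Hochberg step-up written out by its definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):  # enforce step-up monotonicity
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def oracle_deviations(n_instances: int = 1000, seed: int = 0) -> dict[str, float]:
    """Max abs deviation of the fast paths from the naive oracles on random
    small instances (vector lengths 4-30, p-vectors up to length 50)."""
    rng = np.random.default_rng(seed)
    dev_bc = dev_sp = dev_bh = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 31))
        a = rng.random(n) * rng.choice([1.0, 10.0])
        b = rng.random(n)
        dev_bc = max(dev_bc, abs(community_analysis.bray_curtis(a, b) - bray_curtis_reference(a, b)))
        x = rng.integers(0, 8, n).astype(float)  # integer draws force ties
        y = rng.integers(0, 8, n).astype(float) + 0.1 * rng.random(n)
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            rho, _ = taxon_function.spearman(x, y)
            dev_sp = max(dev_sp, abs(rho - spearman_rho_reference(x, y)))
        m = int(rng.integers(1, 51))
        p = rng.random(m)
        dev_bh = max(dev_bh, float(np.max(np.abs(association.fdr_bh(p) - fdr_bh_reference(p)))))
    return {"bray_curtis": dev_bc, "spearman": dev_sp, "fdr_bh": dev_bh}


# ---------------------------------------------------------------------------
# simulation studies


def _sub_seed(base_seed: int, offset: int) -> int:
    return int((base_seed * 10_000 + offset) % (2**31 - 1))


def association_recovery(
    n_seeds: int = 20,
    base_seed: int = 1,
    effect_size: float = 0.5,
    noise_sd: float = 0.1,
    n_species: int = 50,
) -> dict[str, float]:
    """Planted BMI-species effect recovery and null false-call fraction.

    Each replicate is a 20-pair single-time-point cohort (40 samples) with
    one planted negative BMI effect of |beta| = ``effect_size`` on the
    arcsin-sqrt scale at residual SD ``noise_sd``.  Recovery means the
    planted (species, bmi) pair is reported with a negative coefficient and
    q < 0.2.  The null runs the same cohorts without planted effects and
    reports the mean number of q < 0.2 calls per screened feature (the
    screen-level false-call fraction; the per-test fraction is not a
    calibrated quantity here because only boosting-selected variables are
    ever tested).
    """
    planted_species = species_name(0)
    hits = 0
    null_fracs: list[float] = []
    for s in range(n_seeds):
        cfg = CohortConfig(
            n_pairs=20,
            n_timepoints=1,
            n_dropped_samples=0,
            n_species=n_species,
            n_modules=5,
            n_markers_per_species=5,
            planted_effects=(PlantedEffect("bmi", planted_species, -1, effect_size),),
            noise_sd=noise_sd,
            seed=_sub_seed(base_seed, s),
        )
        cohort = generate_cohort(cfg)
        res = association.run_association(cohort.abundance, cohort.metadata)
        hit = res[(res["feature"] == planted_species) & (res["variable"] == "bmi")]
        if len(hit) and float(hit["coefficient"].iloc[0]) < 0 and float(hit["q"].iloc[0]) < 0.2:
            hits += 1
        null_cohort = generate_cohort(
            CohortConfig(
                n_pairs=20,
                n_timepoints=1,
                n_dropped_samples=0,
                n_species=n_species,
                n_modules=5,
                n_markers_per_species=5,
                noise_sd=noise_sd,
                seed=_sub_seed(base_seed, 5000 + s),
            )
        )
        null_res = association.run_association(null_cohort.abundance, null_cohort.metadata)
        n_features = association.filter_features(null_cohort.abundance).data.shape[1]
        null_fracs.append(float((null_res["q"] < 0.2).sum()) / n_features if len(null_res) else 0.0)
    return {
        "recovery_rate": hits / n_seeds,
        "null_call_fraction": float(np.mean(null_fracs)),
        "n_seeds": n_seeds,
    }


def _strain_cohort(seed: int, twin_divergence: float, self_divergence: float,
                   twin_species_correlation: float) -> CohortConfig:
    return CohortConfig(
        n_pairs=10,
        n_timepoints=2,
        n_dropped_samples=4,
        n_species=12,
        n_modules=5,
        n_markers_per_species=60,
        twin_species_correlation=twin_species_correlation,
        strain_twin_divergence=twin_divergence,
        strain_self_divergence=self_divergence,
        seed=seed,
    )


def strain_contrast_study(n_seeds: int = 50, base_seed: int = 1) -> dict[str, float]:
    """Power and null rates for the pooled strain-distance group contrasts.

    Power condition: stable self strains (divergence 0) vs twin divergence
    0.3 — twin-vs-self Welch p < 0.01 expected.  Null condition: twin strain
    divergence raised to the unrelated ceiling 2p(1-p) and twin species
    correlation removed, so twins are strain- and composition-wise unrelated
    — twin-vs-unrelated p > 0.05 expected.
    """
    power_hits = 0
    null_hits = 0
    for s in range(n_seeds):
        cohort = generate_cohort(
            _strain_cohort(_sub_seed(base_seed, s), twin_divergence=0.3, self_divergence=0.0,
                           twin_species_correlation=0.5)
        )
        pairs = community_analysis.enumerate_pairs(cohort.metadata)
        comp = strain_fingerprint.strain_comparisons(cohort.markers, pairs)
        gc = strain_fingerprint.compare_strain_groups(comp)
        if gc.tests[("twin", "self")][1] < 0.01:
            power_hits += 1

        null_div = unrelated_divergence(0.8)
        cohort = generate_cohort(
            _strain_cohort(_sub_seed(base_seed, 5000 + s), twin_divergence=null_div,
                           self_divergence=0.0, twin_species_correlation=0.0)
        )
        pairs = community_analysis.enumerate_pairs(cohort.metadata)
        comp = strain_fingerprint.strain_comparisons(cohort.markers, pairs)
        gc = strain_fingerprint.compare_strain_groups(comp)
        if gc.tests[("unrelated", "twin")][1] > 0.05:
            null_hits += 1
    return {
        "twin_self_power_rate": power_hits / n_seeds,
        "twin_unrelated_null_rate": null_hits / n_seeds,
        "n_seeds": n_seeds,
    }


def classification_recovery(n_seeds: int = 20, base_seed: int = 1) -> dict[str, float]:
    """Encoded/associated classification recovery under low-noise modules.

    For each replicate, modules are generated from a known binary carriage
    matrix at noise SD 0.05.  Checked: (a) every significant positive
    carrier-module record is classified encoded; (b) among significant
    positive records of non-carriers that share a co-occurrence group with a
    carrier of the module, the fraction classified associated.
    """
    encoded_ok = 0
    assoc_num = 0
    assoc_den = 0
    for s in range(n_seeds):
        cfg = CohortConfig(
            n_pairs=10,
            n_timepoints=2,
            n_dropped_samples=4,
            n_species=21,
            n_modules=15,
            n_markers_per_species=5,
            noise_sd=0.05,
            seed=_sub_seed(base_seed, s),
        )
        cohort = generate_cohort(cfg)
        records = taxon_function.correlation_matrix(cohort.abundance, cohort.functions)
        network = taxon_function.cooccurrence_network(cohort.abundance)
        records = taxon_function.classify_correlations(records, cohort.carriage, network)
        carr = cohort.carriage.data
        groups = cohort.truth.cooccurrence_group
        sig_pos = records[(records["tier"] != "none") & (records["rho"] > 0)]
        carrier_rows = sig_pos[sig_pos["carriage"] >= 0.5]
        if (carrier_rows["class"] == "encoded").all():
            encoded_ok += 1
        for _, row in sig_pos[sig_pos["carriage"] < 0.5].iterrows():
            taxon, module = row["taxon"], row["module"]
            carriers = set(carr.index[carr[module] >= 0.5])
            same_group = {t for t in carriers if groups.get(t) == groups.get(taxon)} - {taxon}
            if same_group:
                assoc_den += 1
                if row["class"] == "associated":
                    assoc_num += 1
    return {
        "encoded_all_rate": encoded_ok / n_seeds,
        "associated_fraction": assoc_num / assoc_den if assoc_den else float("nan"),
        "n_associated_records": assoc_den,
        "n_seeds": n_seeds,
    }


def community_ordering(n_seeds: int = 50, base_seed: int = 1) -> dict[str, float]:
    """Fraction of seeds with mean(self) < mean(twin) < mean(unrelated)
    species-level Bray-Curtis distances on default twin cohorts with stable
    self strains."""
    hits = 0
    for s in range(n_seeds):
        cohort = generate_cohort(
            CohortConfig(strain_self_divergence=0.0, n_markers_per_species=5,
                         seed=_sub_seed(base_seed, s))
        )
        dm = community_analysis.distance_matrix(cohort.abundance)
        pairs = community_analysis.enumerate_pairs(cohort.metadata)
        vals = community_analysis.pair_distance_values(pairs, dm)
        m = {t: float(np.mean(v)) for t, v in vals.items()}
        if m["self"] < m["twin"] < m["unrelated"]:
            hits += 1
    return {"ordering_rate": hits / n_seeds, "n_seeds": n_seeds}


def correlation_cardinality(n_taxa: int = 56, n_modules: int = 87, seed: int = 1) -> int:
    """Number of correlation records for an ``n_taxa`` x ``n_modules`` input."""
    cfg = CohortConfig(
        n_species=n_taxa, n_modules=n_modules, n_markers_per_species=5, seed=seed
    )
    cohort = generate_cohort(cfg)
    records = taxon_function.correlation_matrix(cohort.abundance, cohort.functions)
    return int(len(records))
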