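"""Strain-level comparison via clade-specific marker-gene abundance barcodes.

A strain is fingerprinted by which of its species' marker genes are present
(gene gain/loss means an individual strain does not carry every marker of
its species).  Marker abundance is expressed in reads per kilobase of marker
gene (RPK); with 100-nt reads, 10 RPK corresponds to about x1 fold coverage.
A (species, sample) enters comparisons only when the median RPK over *all*
the species' markers — zeros included — is strictly above a threshold
(default 5 RPK, about half-fold coverage), so that absence calls are not
sequencing-depth artefacts.  Distances between eligible marker profiles are
Bray-Curtis over the full RPK vectors, pooled across species for the
unrelated/twin/self group tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .community_analysis import GroupComparison, PairSet, bray_curtis, compare_groups
from .profile_io import MarkerProfileSet

__all__ = [
    "MarkerVector",
    "StrainComparison",
    "Barcode",
    "marker_rpk",
    "rpk_to_coverage",
    "eligible_comparisons",
    "strain_distance",
    "strain_comparisons",
    "make_barcode",
    "barcode_diff",
    "barcode_discordance_table",
    "compare_strain_groups",
    "species_mean_divergence",
    "LEVELS",
]

LEVELS = ("absent", "low", "mid", "high")


@dataclass
class MarkerVector:
    """Per-marker RPK profile of one species in one sample."""

    species: str
    sample_id: str
    rpk: pd.Series

    def __post_init__(self) -> None:
        self.rpk = self.rpk.astype(float)
        if (self.rpk < 0).any():
            raise ValueError("RPK values must be non-negative")


@dataclass
class StrainComparison:
    species: str
    sample_a: str
    sample_b: str
    pair_type: str
    distance: float


@dataclass
class Barcode:
    """Presence flags and four-level abundance bins of one strain fingerprint."""

    species: str
    sample_id: str
    levels: pd.Series  # marker -> one of LEVELS

    @property
    def presence(self) -> pd.Series:
        return self.levels != "absent"


def marker_rpk(read_count: float, marker_length: float) -> float:
    """Reads per kilobase: mapped reads normalised by marker length (nt)."""
    if marker_length <= 0:
        raise ValueError("marker_length must be positive")
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    return read_count / (marker_length / 1000.0)


def rpk_to_coverage(rpk: float, read_length: float = 100.0) -> float:
    """Approximate fold coverage of a marker: RPK x read length / 1000."""
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if rpk < 0:
        raise ValueError("rpk must be non-negative")
    return rpk * read_length / 1000.0


def eligible_comparisons(
    markers: MarkerProfileSet, pairs: PairSet, min_median_rpk: float = 5.0
) -> list[tuple[str, str, str, str]]:
    """(species, sample_a, sample_b, pair_type) tuples where both samples pass.

    A (species, sample) passes iff the median RPK over all the species'
    markers, zeros included, is strictly greater than ``min_median_rpk``.
    Raising the threshold never adds comparisons.
    """
    out: list[tuple[str, str, str, str]] = []
    for species in markers.species:
        table = markers[species]
        medians = table.median(axis=1)
        passing = set(medians.index[medians > min_median_rpk])
        for a, b, pair_type in pairs.pairs:
            if a in passing and b in passing:
                out.append((species, a, b, pair_type))
    return out


def strain_distance(a: MarkerVector, b: MarkerVector) -> float:
    """Bray-Curtis distance over the full marker RPK vectors of one species."""
    if a.species != b.species:
        raise ValueError(f"species mismatch: {a.species!r} vs {b.species!r}")
    if list(a.rpk.index) != list(b.rpk.index):
        raise ValueError("marker sets differ")
    return bray_curtis(a.rpk.to_numpy(), b.rpk.to_numpy())


def strain_comparisons(
    markers: MarkerProfileSet, pairs: PairSet, min_median_rpk: float = 5.0
) -> list[StrainComparison]:
    """Distances for every eligible (species, sample pair)."""
    out: list[StrainComparison] = []
    for species, a, b, pair_type in eligible_comparisons(markers, pairs, min_median_rpk):
        table = markers[species]
        d = bray_curtis(table.loc[a].to_numpy(), table.loc[b].to_numpy())
        out.append(StrainComparison(species, a, b, pair_type, d))
    return out


def make_barcode(
    v: MarkerVector,
    presence_min_rpk: float = 0.0,
    level_bounds: tuple[float, float] = (1.0, 10.0),
) -> Barcode:
    """Bin a marker profile into absent / low / mid / high levels.

    A marker is present iff RPK > ``presence_min_rpk``; present markers are
    binned at ``level_bounds`` (default 1 and 10 RPK — 10 RPK is the x1
    coverage anchor for 100-nt reads).  Bins are for reporting only;
    distances never use them.
    """
    b1, b2 = level_bounds
    if not b1 < b2:
        raise ValueError(f"level_bounds must be increasing, got {level_bounds}")
    rpk = v.rpk.to_numpy()
    levels = np.where(
        rpk <= presence_min_rpk, "absent", np.where(rpk <= b1, "low", np.where(rpk <= b2, "mid", "high"))
    )
    return Barcode(species=v.species, sample_id=v.sample_id, levels=pd.Series(levels, index=v.rpk.index))


def barcode_diff(a: Barcode, b: Barcode, label: str = "discordant") -> pd.DataFrame:
    """Per-marker difference report between two barcodes of the same species.

    Markers present in exactly one of the two samples are marked: with the
    default label for twin comparisons ("twin-discordant" semantics), or any
    caller-supplied label, e.g. "self-discordant" for same-subject time
    points.
    """
    if a.species != b.species:
        raise ValueError(f"species mismatch: {a.species!r} vs {b.species!r}")
    if list(a.levels.index) != list(b.levels.index):
        raise ValueError("marker sets differ")
    pa, pb = a.presence, b.presence
    out = pd.DataFrame(
        {
            "marker": a.levels.index,
            "level_a": a.levels.to_numpy(),
            "level_b": b.levels.to_numpy(),
            "present_a": pa.to_numpy(),
            "present_b": pb.to_numpy(),
            label: (pa ^ pb).to_numpy(),
        }
    )
    return out


def barcode_discordance_table(
    markers: MarkerProfileSet,
    comparisons: Sequence[StrainComparison],
    presence_min_rpk: float = 0.0,
    level_bounds: tuple[float, float] = (1.0, 10.0),
) -> pd.DataFrame:
    """Per-comparison barcode discordance counts for twin and self pairs.

    For every twin/self comparison, bins both samples' marker profiles and
    counts markers present in exactly one of the two — the quantity the
    barcode difference displays highlight.
    """
    rows = []
    for c in comparisons:
        if c.pair_type == "unrelated":
            continue
        table = markers[c.species]
        a = make_barcode(MarkerVector(c.species, c.sample_a, table.loc[c.sample_a]),
                         presence_min_rpk, level_bounds)
        b = make_barcode(MarkerVector(c.species, c.sample_b, table.loc[c.sample_b]),
                         presence_min_rpk, level_bounds)
        diff = barcode_diff(a, b)
        rows.append((c.species, c.sample_a, c.sample_b, c.pair_type,
                     int(diff["discordant"].sum()), len(diff)))
    return pd.DataFrame(
        rows,
        columns=["species", "sample_a", "sample_b", "pair_type",
                 "n_discordant_markers", "n_markers"],
    )


def compare_strain_groups(
    comparisons: Sequence[StrainComparison],
    contrasts: Sequence[tuple[str, str]] = (("unrelated", "twin"), ("twin", "self")),
) -> GroupComparison:
    """Group means and Welch t-tests over pooled strain distances."""
    values: dict[str, list[float]] = {}
    for c in comparisons:
        values.setdefault(c.pair_type, []).append(c.distance)
    return compare_groups(values, contrasts=contrasts)


def species_mean_divergence(comparisons: Sequence[StrainComparison]) -> pd.DataFrame:
    """Mean strain distance and comparison count per (species, pair type)."""
    df = pd.DataFrame(
        [(c.species, c.pair_type, c.distance) for c in comparisons],
        columns=["species", "pair_type", "distance"],
    )
    if df.empty:
        return pd.DataFrame(columns=["species", "pair_type", "mean_distance", "n"])
    grouped = (
        df.groupby(["species", "pair_type"], observed=True)["distance"]
        .agg(mean_distance="mean", n="count")
        .reset_index()
    )
    return grouped
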