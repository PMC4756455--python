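"""Community-level ecology on relative-abundance profiles.

Bray-Curtis dissimilarities, classical principal-coordinates (metric MDS)
ordination, unrelated/twin/self group contrasts of composition and clinical
values, and two-cohort prevalence / conditional-abundance comparison.

Pair-type conventions: *self* pairs are the same subject at the two time
points; *twin* pairs are the two co-twins at time point 1; *unrelated* pairs
are members of different twin pairs, also restricted to time point 1.  The
non-independence of pairwise distances within these groups is deliberately
ignored in the t-tests, matching common practice for this kind of figure;
see the methods note for the caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

import skbio
from skbio.stats.ordination import pcoa

from .profile_io import AbundanceTable, MetadataTable

__all__ = [
    "DistanceMatrix",
    "PairSet",
    "GroupComparison",
    "CohortSummary",
    "OrdinationResult",
    "bray_curtis",
    "distance_matrix",
    "ordinate",
    "enumerate_pairs",
    "pair_distance_values",
    "pair_difference_values",
    "compare_groups",
    "welch_t",
    "summarize_cohort",
    "compare_cohorts",
    "PAIR_TYPES",
]

PAIR_TYPES = ("unrelated", "twin", "self")
DEFAULT_CONTRASTS = (("unrelated", "twin"), ("twin", "self"))


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with named metric."""

    ids: list[str]
    values: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def between(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class PairSet:
    """Typed sample pairs: (sample_a, sample_b, pair_type)."""

    pairs: list[tuple[str, str, str]]

    def by_type(self, pair_type: str) -> list[tuple[str, str]]:
        return [(a, b) for a, b, t in self.pairs if t == pair_type]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class GroupComparison:
    """Group values, means and Welch t-tests for the requested contrasts."""

    values: dict[str, list[float]]
    means: dict[str, float]
    tests: dict[tuple[str, str], tuple[float, float]]  # contrast -> (t, p)


@dataclass
class CohortSummary:
    """Per-clade prevalence (%) and conditional mean abundance above a threshold."""

    table: pd.DataFrame  # index clade, columns: prevalence, conditional_mean
    threshold: float


@dataclass
class OrdinationResult:
    """PCoA embedding: sample coordinates and retained (positive) eigenvalues."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) over non-negative vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("Bray-Curtis requires non-negative vectors")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined: both vectors are all-zero")
    return float(np.abs(a - b).sum() / denom)


def _as_matrix(table) -> tuple[list[str], np.ndarray]:
    if isinstance(table, AbundanceTable):
        return table.sample_ids, table.data.to_numpy()
    if isinstance(table, pd.DataFrame):
        return [str(i) for i in table.index], table.to_numpy(dtype=float)
    arr = np.asarray(table, dtype=float)
    return [str(i) for i in range(arr.shape[0])], arr


def distance_matrix(table, metric: str = "braycurtis") -> DistanceMatrix:
    """All-pairs distance matrix over the rows of a samples x features table."""
    ids, x = _as_matrix(table)
    zero_rows = np.asarray(ids)[x.sum(axis=1) == 0]
    if metric == "braycurtis" and zero_rows.size:
        raise ValueError(f"all-zero sample rows: {list(zero_rows)}")
    d = squareform(pdist(x, metric=metric))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(ids), values=d, metric=metric)


def ordinate(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical PCoA (metric MDS) of a distance matrix.

    Axes with eigenvalue below 1e-10 (including the negative axes a
    non-Euclidean semimetric produces) are dropped; retained axes are ordered
    by decreasing eigenvalue and padded with zero columns up to ``k``.  Axis
    orientation is fixed by making each axis's largest-magnitude coordinate
    positive.
    """
    n = len(dm.ids)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must lie in [1, {n - 1}], got {k}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = pcoa(skbio.DistanceMatrix(dm.values, ids=dm.ids), method="eigh")
    eig = res.eigvals.to_numpy()
    coords = res.samples.to_numpy()
    order = np.argsort(eig)[::-1]
    eig, coords = eig[order], coords[:, order]
    keep = eig > 1e-10
    eig, coords = eig[keep], coords[:, keep]
    for j in range(coords.shape[1]):  # reproducible orientation
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    out = np.zeros((n, k))
    m = min(k, coords.shape[1])
    out[:, :m] = coords[:, :m]
    frame = pd.DataFrame(out, index=dm.ids, columns=[f"PC{i + 1}" for i in range(k)])
    return OrdinationResult(coordinates=frame, eigenvalues=eig)


def enumerate_pairs(metadata: MetadataTable) -> PairSet:
    """All typed sample pairs: self across time, twin and unrelated at time point 1."""
    df = metadata.data
    pairs: list[tuple[str, str, str]] = []
    for _, grp in df.groupby("subject_id", observed=True):
        if len(grp) == 2:
            g = grp.sort_values("timepoint")
            pairs.append((g.index[0], g.index[1], "self"))
    if not any(t == "self" for *_, t in pairs):
        warnings.warn("no subjects with two time points: self group is empty", stacklevel=2)
    t1 = df[df["timepoint"] == 1].sort_index()
    ids = list(t1.index)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            same_pair = t1.at[a, "pair_id"] == t1.at[b, "pair_id"]
            same_subj = t1.at[a, "subject_id"] == t1.at[b, "subject_id"]
            if same_subj:
                continue
            pairs.append((a, b, "twin" if same_pair else "unrelated"))
    return PairSet(pairs=pairs)


def pair_distance_values(pairs: PairSet, dm: DistanceMatrix) -> dict[str, list[float]]:
    """Per-pair-type lists of distances looked up from a distance matrix."""
    idx = {s: i for i, s in enumerate(dm.ids)}
    out: dict[str, list[float]] = {t: [] for t in PAIR_TYPES}
    for a, b, t in pairs.pairs:
        out[t].append(float(dm.values[idx[a], idx[b]]))
    return out


def pair_difference_values(
    pairs: PairSet, metadata: MetadataTable, column: str
) -> dict[str, list[float]]:
    """Per-pair-type absolute differences of a per-sample scalar (e.g. |dBMI|)."""
    s = metadata.data[column]
    out: dict[str, list[float]] = {t: [] for t in PAIR_TYPES}
    for a, b, t in pairs.pairs:
        va, vb = s.at[a], s.at[b]
        if pd.notna(va) and pd.notna(vb):
            out[t].append(abs(float(va) - float(vb)))
    return out


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p, degenerate-safe.

    When both groups have zero variance the statistic is defined by
    continuity: equal means give (0, 1), unequal means (+/-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    from scipy.stats import ttest_ind

    t, p = ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
) -> GroupComparison:
    """Welch t-test for each contrast of per-group scalar values."""
    contrasts = [tuple(c) for c in contrasts]
    tests: dict[tuple[str, str], tuple[float, float]] = {}
    for ga, gb in contrasts:
        for g in (ga, gb):
            if len(values_by_group.get(g, [])) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 values")
        tests[(ga, gb)] = welch_t(values_by_group[ga], values_by_group[gb])
    means = {g: float(np.mean(v)) for g, v in values_by_group.items() if len(v)}
    return GroupComparison(
        values={g: [float(x) for x in v] for g, v in values_by_group.items()},
        means=means,
        tests=tests,
    )


def summarize_cohort(table: AbundanceTable, threshold: float = 0.001) -> CohortSummary:
    """Per-clade prevalence (% of samples strictly above ``threshold``) and the
    mean abundance over only those passing samples (NaN when never present)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    x = table.data
    passing = x > threshold
    prevalence = passing.mean(axis=0) * 100.0
    conditional = x.where(passing).mean(axis=0)
    out = pd.DataFrame({"prevalence": prevalence, "conditional_mean": conditional})
    out.index.name = "clade"
    return CohortSummary(table=out, threshold=threshold)


def compare_cohorts(a: CohortSummary, b: CohortSummary) -> dict[str, tuple[float, float]]:
    """Pearson correlation of prevalence and conditional abundance over shared clades."""
    shared = a.table.index.intersection(b.table.index)
    out: dict[str, tuple[float, float]] = {}
    for column in ("prevalence", "conditional_mean"):
        va = a.table.loc[shared, column]
        vb = b.table.loc[shared, column]
        ok = va.notna() & vb.notna()
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 shared clades with defined {column}")
        xa, xb = va[ok].to_numpy(), vb[ok].to_numpy()
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            raise ValueError(f"constant {column} vector: correlation undefined")
        r, p = pearsonr(xa, xb)
        out[column] = (float(r), float(p))
    return out
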