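"""Taxon x function correlation matrix and its encoded/associated classification.

Every species profile is Spearman-correlated against every KEGG-module
profile; cells are marked significant at two tiers (nominal p < 0.01, BH FDR
q < 0.2, the BH family being the whole matrix).  Each significant *positive*
correlation is then explained, if possible, by genome content:

* **encoded** — the fraction of the taxon's reference genomes carrying the
  module (the carriage matrix) reaches ``encoded_threshold``;
* **associated** — not encoded, but the taxon has a significant-positive
  co-occurrence edge to at least one taxon whose own record for that module
  is encoded;
* **unexplained** — neither.

Negative or non-significant records are left ``not-classified`` (negative
correlations are reported, but no formal rule classifies them; the
co-occurrence network can be inspected for anti-correlations).  The taxon
co-occurrence network is Spearman over taxa profiles with its own BH family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .association import fdr_bh
from .profile_io import AbundanceTable, CarriageMatrix, FunctionTable, species_short_name

__all__ = [
    "CooccurrenceNetwork",
    "spearman",
    "correlation_matrix",
    "cooccurrence_network",
    "classify_correlations",
    "cross_cohort_overlap",
    "TIERS",
    "CLASSES",
]

TIERS = ("none", "nominal", "fdr")
CLASSES = ("encoded", "associated", "unexplained", "not-classified")


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected (average-rank) Spearman rho with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for a constant input")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class CooccurrenceNetwork:
    """Taxon x taxon Spearman correlations and the significant-positive edges."""

    taxa: list[str]
    rho: pd.DataFrame
    q: pd.DataFrame
    edges: set[frozenset]

    def neighbors(self, taxon: str) -> set[str]:
        return {next(iter(e - {taxon})) for e in self.edges if taxon in e}


def _drop_constant(df: pd.DataFrame, what: str) -> pd.DataFrame:
    sd = df.std(axis=0, ddof=0)
    constant = list(sd[sd == 0].index)
    if constant:
        warnings.warn(f"constant {what} excluded from correlation: {constant}", stacklevel=3)
        df = df.drop(columns=constant)
    return df


def correlation_matrix(
    taxa: AbundanceTable,
    modules: FunctionTable,
    p_nominal: float = 0.01,
    q_threshold: float = 0.2,
) -> pd.DataFrame:
    """All taxon x module Spearman correlations with tier marks.

    Returns one row per (taxon, module) cell with columns ``taxon``,
    ``module``, ``rho``, ``p``, ``q`` and ``tier``; the BH family is the full
    matrix.  Taxon names are leaf clade names (lineage prefixes stripped).
    """
    shared = taxa.data.index.intersection(modules.data.index)
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    tx = taxa.data.loc[shared]
    tx.columns = [species_short_name(c) for c in tx.columns]
    md = modules.data.loc[shared]
    tx = _drop_constant(tx, "taxa")
    md = _drop_constant(md, "modules")
    nt, nm = tx.shape[1], md.shape[1]
    rho_full, p_full = spearmanr(tx.to_numpy(), md.to_numpy())
    rho = np.atleast_2d(rho_full)[:nt, nt:]
    p = np.atleast_2d(p_full)[:nt, nt:]
    records = pd.DataFrame(
        {
            "taxon": np.repeat(list(tx.columns), nm),
            "module": np.tile(list(md.columns), nt),
            "rho": rho.ravel(),
            "p": p.ravel(),
        }
    )
    records["q"] = fdr_bh(records["p"].to_numpy())
    records["tier"] = np.where(
        records["q"] < q_threshold, "fdr", np.where(records["p"] < p_nominal, "nominal", "none")
    )
    return records


def cooccurrence_network(taxa: AbundanceTable, q_threshold: float = 0.2) -> CooccurrenceNetwork:
    """Taxon co-occurrence: Spearman over taxa profiles, BH within the network,
    significant-positive edges at ``q < q_threshold`` and ``rho > 0``."""
    tx = taxa.data.copy()
    tx.columns = [species_short_name(c) for c in tx.columns]
    tx = _drop_constant(tx, "taxa")
    names = list(tx.columns)
    if len(names) < 3:
        raise ValueError("need at least 3 taxa for a co-occurrence network")
    rho, p = spearmanr(tx.to_numpy())
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    iu = np.triu_indices(len(names), k=1)
    q_flat = fdr_bh(p[iu])
    q = np.ones_like(p)
    q[iu] = q_flat
    q[(iu[1], iu[0])] = q_flat
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(rho, 1.0)
    edges = {
        frozenset((names[i], names[j]))
        for i, j, qv in zip(*iu, q_flat)
        if qv < q_threshold and rho[i, j] > 0
    }
    return CooccurrenceNetwork(
        taxa=names,
        rho=pd.DataFrame(rho, index=names, columns=names),
        q=pd.DataFrame(q, index=names, columns=names),
        edges=edges,
    )


def classify_correlations(
    records: pd.DataFrame,
    carriage: CarriageMatrix,
    network: CooccurrenceNetwork,
    encoded_threshold: float = 0.5,
) -> pd.DataFrame:
    """Attach ``class`` and ``carriage`` columns to a correlation-record table.

    Missing carriage cells are treated as 0 with a warning.  Classification
    is exhaustive and mutually exclusive over significant positive records;
    everything else is ``not-classified``.
    """
    out = records.copy().reset_index(drop=True)
    carr = np.array(
        [carriage.fraction(t, m) for t, m in zip(out["taxon"], out["module"])], dtype=float
    )
    if np.isnan(carr).any():
        missing = sorted(
            {(t, m) for t, m, c in zip(out["taxon"], out["module"], carr) if np.isnan(c)}
        )
        warnings.warn(
            f"{len(missing)} taxon-module cells missing from carriage matrix, treated as 0",
            stacklevel=2,
        )
        carr = np.nan_to_num(carr, nan=0.0)
    out["carriage"] = carr
    significant_pos = (out["tier"] != "none") & (out["rho"] > 0)
    encoded_mask = significant_pos & (out["carriage"] >= encoded_threshold)
    # taxa with an encoded record per module, for the 'associated' pass
    encoded_by_module: dict[str, set[str]] = {}
    for t, m in zip(out.loc[encoded_mask, "taxon"], out.loc[encoded_mask, "module"]):
        encoded_by_module.setdefault(m, set()).add(t)
    classes = np.full(len(out), "not-classified", dtype=object)
    classes[encoded_mask.to_numpy()] = "encoded"
    rest = significant_pos & ~encoded_mask
    for i in np.flatnonzero(rest.to_numpy()):
        taxon, module = out.at[i, "taxon"], out.at[i, "module"]
        carriers = encoded_by_module.get(module, set())
        if carriers & network.neighbors(taxon):
            classes[i] = "associated"
        else:
            classes[i] = "unexplained"
    out["class"] = classes
    return out


def cross_cohort_overlap(
    records_a: pd.DataFrame, records_b: pd.DataFrame, tier: str = "fdr"
) -> pd.DataFrame:
    """Significant (taxon, module) pairs shared by two cohorts at a tier.

    A pair matches only when significant at (at least) the requested tier in
    both cohorts *and* with the same correlation sign; a sign-flipped
    duplicate is excluded.
    """
    if tier not in TIERS[1:]:
        raise ValueError(f"tier must be one of {TIERS[1:]}, got {tier!r}")
    rank = {t: i for i, t in enumerate(TIERS)}
    need = rank[tier]

    def significant(df: pd.DataFrame) -> pd.DataFrame:
        keep = df["tier"].map(rank) >= need
        sub = df.loc[keep, ["taxon", "module", "rho"]].copy()
        sub["sign"] = np.sign(sub["rho"]).astype(int)
        return sub

    a = significant(records_a)
    b = significant(records_b)
    merged = a.merge(b, on=["taxon", "module", "sign"], suffixes=("_a", "_b"))
    return merged[["taxon", "module", "sign", "rho_a", "rho_b"]].reset_index(drop=True)
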