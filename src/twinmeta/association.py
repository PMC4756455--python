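"""Multivariate association of microbial features with clinical variables.

The model follows the sparse multivariate-linear-model recipe used for
microbiome-phenotype screens: per feature, arcsin-square-root transform of
the relative abundance, componentwise-boosting selection over the candidate
clinical variables, then a linear mixed model with the selected variables
plus forced confounders (age, sex, smoking) as fixed effects and the twin
pair as a random intercept.  p-values are Wald tests per fixed effect;
Benjamini-Hochberg FDR is applied across all (feature, variable) tests of a
run as one family.

Features are pre-filtered on abundance and prevalence; samples with missing
clinical values are dropped per model, not globally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .profile_io import (
    AbundanceTable,
    CATEGORICAL_VARIABLES,
    CLINICAL_VARIABLES,
    FunctionTable,
    MetadataTable,
)

__all__ = [
    "AssociationConfig",
    "FeatureModelFit",
    "arcsin_sqrt",
    "filter_features",
    "select_covariates",
    "fit_feature_model",
    "fdr_bh",
    "run_association",
]


@dataclass(frozen=True)
class AssociationConfig:
    """Settings of one association run.

    Boosting defaults (1000 iterations, learning rate 0.01, selection at 5 %
    of iterations) mirror the published defaults of the reference tool at the
    level its description states them; all are configurable.
    """

    covariates_forced: tuple[str, ...] = ("age", "sex", "smoking")
    candidates: tuple[str, ...] | None = None  # None -> all clinical variables present
    random_effect: str = "pair_id"
    n_iterations: int = 1000
    learning_rate: float = 0.01
    selection_frequency_threshold: float = 0.05
    min_abundance: float = 0.001
    min_prevalence: float = 0.1
    q_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_abundance", "min_prevalence", "q_threshold",
                     "selection_frequency_threshold"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def arcsin_sqrt(x):
    """Variance-stabilising transform arcsin(sqrt(x)) for proportions in [0, 1]."""
    arr = np.asarray(x, dtype=float)
    if ((arr < -1e-12) | (arr > 1 + 1e-12)).any():
        raise ValueError("arcsin_sqrt input must lie in [0, 1]")
    out = np.arcsin(np.sqrt(np.clip(arr, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def filter_features(table, min_abundance: float = 0.001, min_prevalence: float = 0.1):
    """Keep features exceeding ``min_abundance`` in more than ``min_prevalence``
    of samples (both comparisons strict)."""
    data = table.data
    frac = (data > min_abundance).mean(axis=0)
    keep = data.columns[frac > min_prevalence]
    if len(keep) == 0:
        warnings.warn("no features pass the abundance/prevalence filter", stacklevel=2)
    out = data.loc[:, keep]
    if isinstance(table, AbundanceTable):
        return AbundanceTable(data=out, rank=table.rank)
    return FunctionTable(data=out)


def select_covariates(
    y: np.ndarray,
    candidates: pd.DataFrame,
    n_iterations: int = 1000,
    learning_rate: float = 0.01,
    selection_frequency_threshold: float = 0.05,
    seed: int | None = None,
    bag_fraction: float = 1.0,
) -> list[str]:
    """Componentwise L2 gradient boosting with univariate linear base learners.

    At each iteration the single candidate that best fits the current
    residual is updated by ``learning_rate`` times its least-squares fit.
    The boosting path is stopped at the step minimising a BIC along the path
    (residual fit penalised by the number of distinct candidates entered);
    without a stopping rule slow componentwise boosting converges to the
    saturated least-squares fit and would select every candidate under the
    null.  A candidate is selected if it was chosen in at least
    ``selection_frequency_threshold`` of the retained iterations.  The
    procedure is deterministic unless ``bag_fraction < 1``, in which case
    each iteration scores candidates on a random row subsample drawn from
    ``seed``.
    """
    if candidates.shape[1] == 0:
        return []
    y = np.asarray(y, dtype=float)
    sd = candidates.std(axis=0, ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"zero-variance candidates excluded: {list(constant)}", stacklevel=2)
        candidates = candidates.drop(columns=constant)
        if candidates.shape[1] == 0:
            return []
    names = list(candidates.columns)
    x = (candidates.to_numpy(dtype=float) - candidates.to_numpy(dtype=float).mean(axis=0))
    x /= x.std(axis=0, ddof=0)
    r = y - y.mean()
    n = y.size
    rng = np.random.default_rng(seed)
    picks = np.empty(n_iterations, dtype=int)
    rss = np.empty(n_iterations)
    for it in range(n_iterations):
        if bag_fraction < 1.0:
            rows = rng.choice(n, size=max(2, int(round(bag_fraction * n))), replace=False)
            score = (x[rows].T @ r[rows]) ** 2
        else:
            score = (x.T @ r) ** 2
        j = int(np.argmax(score))
        picks[it] = j
        beta = (x[:, j] @ r) / n  # columns are standardised, x.x = n
        r = r - learning_rate * beta * x[:, j]
        rss[it] = float(r @ r)
    # BIC along the path; model size = distinct candidates entered so far
    seen: set[int] = set()
    k_path = np.empty(n_iterations, dtype=int)
    for it, j in enumerate(picks):
        seen.add(int(j))
        k_path[it] = len(seen)
    rss0 = float((y - y.mean()) @ (y - y.mean()))
    bic0 = n * math.log(max(rss0, 1e-300) / n) + math.log(n)
    bic = n * np.log(np.maximum(rss, 1e-300) / n) + math.log(n) * (k_path + 1)
    m_star = 0 if bic0 <= bic.min() else int(np.argmin(bic)) + 1
    if m_star == 0:
        return []
    freq = np.bincount(picks[:m_star], minlength=len(names)) / m_star
    return [names[j] for j in range(len(names)) if freq[j] >= selection_frequency_threshold]


@dataclass
class FeatureModelFit:
    """Fixed-effect estimates of one per-feature model."""

    params: pd.Series
    pvalues: pd.Series
    bse: pd.Series
    n: int
    method: str  # "mixed", "ols" or "degenerate"
    dropped: list[str] = field(default_factory=list)


def _encode_design(X: pd.DataFrame) -> pd.DataFrame:
    cat_cols = [c for c in X.columns if X[c].dtype == object or isinstance(X[c].dtype, pd.CategoricalDtype)]
    return pd.get_dummies(X, columns=cat_cols, drop_first=True, dtype=float)


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    kept: list[str] = []
    dropped: list[str] = []
    for col in X.columns:
        trial = X[kept + [col]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(col)
        else:
            dropped.append(col)
    return X[kept], dropped


def fit_feature_model(
    y: np.ndarray, X: pd.DataFrame, groups: Sequence, reml: bool = True
) -> FeatureModelFit:
    """Random-intercept linear mixed model of a transformed feature.

    Falls back to ordinary least squares with a warning when the
    random-intercept variance estimate collapses to zero or the mixed fit
    fails.  Perfectly collinear columns are dropped with a warning; a
    constant response returns zero slopes with p = 1.
    """
    y = np.asarray(y, dtype=float)
    X = _encode_design(X.copy())
    X.insert(0, "const", 1.0)
    X, dropped = _drop_collinear(X)
    if dropped:
        warnings.warn(f"collinear columns dropped: {dropped}", stacklevel=2)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"too few samples (n={n}) for {p} parameters")
    cols = list(X.columns)
    if np.var(y) < 1e-15:
        zeros = pd.Series(0.0, index=cols)
        ones = pd.Series(1.0, index=cols)
        zeros["const"] = float(y.mean())
        return FeatureModelFit(
            params=zeros, pvalues=ones, bse=pd.Series(0.0, index=cols),
            n=n, method="degenerate", dropped=dropped,
        )
    groups = np.asarray(groups)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            mixed = sm.MixedLM(y, X.to_numpy(dtype=float), groups=groups)
            res = mixed.fit(reml=reml, method=["lbfgs", "bfgs"])
        re_var = float(np.asarray(res.cov_re).ravel()[0])
        if not np.isfinite(re_var) or re_var < 1e-8 or not np.all(np.isfinite(res.bse_fe)):
            raise ValueError("random-intercept variance degenerate")
        return FeatureModelFit(
            params=pd.Series(res.fe_params, index=cols),
            pvalues=pd.Series(res.pvalues[: len(cols)], index=cols),
            bse=pd.Series(np.asarray(res.bse_fe), index=cols),
            n=n, method="mixed", dropped=dropped,
        )
    except Exception:
        warnings.warn("mixed model unavailable; falling back to OLS", stacklevel=2)
        res = sm.OLS(y, X.to_numpy(dtype=float)).fit()
        return FeatureModelFit(
            params=pd.Series(res.params, index=cols),
            pvalues=pd.Series(res.pvalues, index=cols),
            bse=pd.Series(res.bse, index=cols),
            n=n, method="ols", dropped=dropped,
        )


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_association(
    features: AbundanceTable | FunctionTable,
    metadata: MetadataTable,
    config: AssociationConfig = AssociationConfig(),
) -> pd.DataFrame:
    """Per-feature transform -> boosting selection -> mixed-model fit -> BH.

    Returns one row per tested (feature, clinical variable): columns
    ``feature``, ``variable``, ``coefficient`` (on the arcsin-sqrt scale),
    ``p``, ``q``, ``n``, ``method``.  Only boosting-selected candidate
    variables are tested and reported; forced confounders are always in the
    model but never reported.  The q-values form one BH family across the
    whole run.
    """
    filtered = filter_features(features, config.min_abundance, config.min_prevalence)
    feature_cols = list(filtered.data.columns)
    if not feature_cols:
        raise ValueError("no features left after abundance/prevalence filtering")
    meta = metadata.data
    candidates = list(config.candidates) if config.candidates is not None else [
        c for c in CLINICAL_VARIABLES if c in meta.columns and c not in config.covariates_forced
    ]
    forced = [c for c in config.covariates_forced if c in meta.columns]
    # canonical sample order makes results exactly invariant to input ordering
    shared = filtered.data.index.intersection(meta.index).sort_values()
    rows: list[dict] = []
    names = filtered.feature_names if hasattr(filtered, "feature_names") else feature_cols
    for col, short in zip(feature_cols, names):
        y_all = arcsin_sqrt(filtered.data.loc[shared, col].to_numpy())
        cand_df = meta.loc[shared, candidates].apply(pd.to_numeric, errors="coerce")
        ok = cand_df.notna().all(axis=1)
        selected = select_covariates(
            y_all[ok.to_numpy()],
            cand_df[ok],
            n_iterations=config.n_iterations,
            learning_rate=config.learning_rate,
            selection_frequency_threshold=config.selection_frequency_threshold,
            seed=config.seed,
        ) if ok.sum() >= 10 else []
        if not selected:
            continue
        model_cols = selected + forced
        sub = meta.loc[shared, model_cols + [config.random_effect]]
        keep = sub[model_cols].notna().all(axis=1)
        sub = sub[keep]
        y = y_all[keep.to_numpy()]
        try:
            fit = fit_feature_model(y, sub[model_cols], sub[config.random_effect].to_numpy())
        except ValueError:
            continue
        for var in selected:
            if var not in fit.params.index:
                continue  # dropped as collinear
            rows.append(
                {
                    "feature": short,
                    "variable": var,
                    "coefficient": float(fit.params[var]),
                    "p": float(fit.pvalues[var]),
                    "n": fit.n,
                    "method": fit.method,
                }
            )
    result = pd.DataFrame(rows, columns=["feature", "variable", "coefficient", "p", "n", "method"])
    if len(result):
        result["q"] = fdr_bh(result["p"].to_numpy())
    else:
        result["q"] = pd.Series(dtype=float)
    result = result.sort_values(["feature", "variable"], kind="stable").reset_index(drop=True)
    return result[["feature", "variable", "coefficient", "p", "q", "n", "method"]]
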