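"""Hierarchical regression of reading skill on network metrics.

Step 1 regresses the pseudo-word decoding efficiency (PDE) score on three
nuisance variables (age in months, task accuracy, response latency).
Step 2 adds the nine connectivity predictors (three graph metrics x three
presentation modalities) and the increment is tested with the nested F
statistic

    F = ((R2_2 - R2_1) / q) / ((1 - R2_2) / df_resid2).

Relative importance of the predictors is decomposed with the LMG method:
a predictor's share is its average sequential contribution to R^2 over
all orderings of the predictors, computed exactly by enumerating all
2^p subsets.  Shares are nonnegative and sum to the full-model R^2.
Pairwise share differences (same metric across modalities, and same
modality across metrics) get percentile bootstrap confidence intervals
from case resampling of subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)

NUISANCE_COLS = ["age_months", "latency_ms", "accuracy"]
MODALITIES = ("VV", "AV", "AA")


def connectivity_columns(
    modalities: tuple[str, ...] = MODALITIES, metrics: tuple[str, ...] = METRIC_NAMES
) -> list[str]:
    """Predictor column order: per metric, modalities in task order."""
    return [f"{mod}_{met}" for met in metrics for mod in modalities]


def metrics_to_wide(metrics: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Pivot a subject x modality metrics table to one row per subject."""
    sub = metrics[metrics["scheme"] == scheme]
    if sub.empty:
        raise ValueError(f"no rows for scheme {scheme!r}")
    wide = sub.pivot(index="subject_id", columns="modality", values=list(METRIC_NAMES))
    wide.columns = [f"{mod}_{met}" for met, mod in wide.columns]
    wide = wide.reset_index()
    if wide.isna().any().any():
        raise ValueError("incomplete subject x modality metric grid")
    return wide


def build_design(
    subjects: pd.DataFrame, metrics: pd.DataFrame, scheme: str
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Join the subject table with wide metrics; return (X, y, added cols)."""
    wide = metrics_to_wide(metrics, scheme)
    merged = subjects.merge(wide, on="subject_id", how="inner", validate="1:1")
    if len(merged) != len(subjects):
        raise ValueError("subject tables and metrics do not cover the same subjects")
    added = [c for c in connectivity_columns() if c in wide.columns]
    X = merged[NUISANCE_COLS + added]
    y = merged["pde"]
    return X, y, added


def _check_full_rank(X: pd.DataFrame) -> None:
    Z = X.to_numpy(dtype=float)
    Z = Z - Z.mean(axis=0)
    rank = np.linalg.matrix_rank(Z)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(np.delete(Z, X.columns.get_loc(c), axis=1)) == rank
        ]
        raise ValueError(f"predictors are rank deficient; collinear columns: {bad}")


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X.astype(float))).fit()


def standardized_betas(y: pd.Series, X: pd.DataFrame) -> pd.Series:
    """OLS slopes after z-scoring outcome and predictors (sample SD)."""
    Xz = (X - X.mean()) / X.std(ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    fit = _ols(yz.to_numpy(), Xz)
    return fit.params.drop("const")


def partial_correlations(fit) -> pd.Series:
    """Signed partial r of each predictor with the outcome given the rest.

    Derived from the coefficient t statistics: r = t / sqrt(t^2 + df).
    """
    t = fit.tvalues.drop("const")
    df = fit.df_resid
    return t / np.sqrt(t**2 + df)


def nested_f(r2_1: float, r2_2: float, q: int, df_resid2: float) -> tuple[float, float]:
    """Nested-model F for the R^2 increment and its p-value."""
    if q <= 0 or df_resid2 <= 0:
        raise ValueError("invalid degrees of freedom for the nested F test")
    with np.errstate(divide="ignore"):  # r2_2 == 1 -> F = inf, p = 0
        f = ((r2_2 - r2_1) / q) / ((1.0 - r2_2) / df_resid2)
    p = float(stats.f.sf(f, q, df_resid2))
    return float(f), p


@dataclass
class HierarchicalFit:
    """Two-step OLS fit with nested comparison and coefficient table."""

    scheme: str
    n: int
    step1: object
    step2: object
    coef_table: pd.DataFrame
    r2_step1: float
    adj_r2_step1: float
    f_step1: tuple[float, int, int, float]  # F, df_model, df_resid, p
    r2_step2: float
    adj_r2_step2: float
    f_step2: tuple[float, int, int, float]
    delta_f: float
    delta_df: tuple[int, int]
    delta_p: float

    def summary_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "n": self.n,
            "step1": {
                "r2": self.r2_step1,
                "adj_r2": self.adj_r2_step1,
                "f": self.f_step1[0],
                "df": [self.f_step1[1], self.f_step1[2]],
                "p": self.f_step1[3],
            },
            "step2": {
                "r2": self.r2_step2,
                "adj_r2": self.adj_r2_step2,
                "f": self.f_step2[0],
                "df": [self.f_step2[1], self.f_step2[2]],
                "p": self.f_step2[3],
            },
            "delta": {
                "f": self.delta_f,
                "df": list(self.delta_df),
                "p": self.delta_p,
            },
        }


def fit_hierarchical(
    subjects: pd.DataFrame, metrics: pd.DataFrame, scheme: str
) -> HierarchicalFit:
    """Two-step hierarchical OLS of PDE on nuisance then connectivity terms."""
    X, y, added = build_design(subjects, metrics, scheme)
    return fit_hierarchical_design(y, X[NUISANCE_COLS], X[added], scheme=scheme)


def fit_hierarchical_design(
    y: pd.Series,
    X_nuisance: pd.DataFrame,
    X_added: pd.DataFrame,
    scheme: str = "design",
) -> HierarchicalFit:
    """Hierarchical fit from an explicit design (step-1 block, added block)."""
    n = len(y)
    X_full = pd.concat([X_nuisance, X_added], axis=1)
    p_total = X_full.shape[1]
    if n <= p_total + 1:
        raise ValueError(f"n={n} too small for {p_total} predictors")
    _check_full_rank(X_full)

    fit1 = _ols(y.to_numpy(), X_nuisance)
    fit2 = _ols(y.to_numpy(), X_full)
    q = X_added.shape[1]
    df_resid2 = fit2.df_resid
    delta_f, delta_p = nested_f(fit1.rsquared, fit2.rsquared, q, df_resid2)

    beta = standardized_betas(y, X_full)
    partial = partial_correlations(fit2)
    coef = pd.DataFrame(
        {
            "B": fit2.params,
            "SE": fit2.bse,
            "beta": beta.reindex(fit2.params.index),
            "partial_r": partial.reindex(fit2.params.index),
            "p": fit2.pvalues,
        }
    )
    coef["partial_r2"] = coef["partial_r"] ** 2

    return HierarchicalFit(
        scheme=scheme,
        n=n,
        step1=fit1,
        step2=fit2,
        coef_table=coef,
        r2_step1=float(fit1.rsquared),
        adj_r2_step1=float(fit1.rsquared_adj),
        f_step1=(float(fit1.fvalue), int(fit1.df_model), int(fit1.df_resid), float(fit1.f_pvalue)),
        r2_step2=float(fit2.rsquared),
        adj_r2_step2=float(fit2.rsquared_adj),
        f_step2=(float(fit2.fvalue), int(fit2.df_model), int(fit2.df_resid), float(fit2.f_pvalue)),
        delta_f=delta_f,
        delta_df=(q, int(df_resid2)),
        delta_p=delta_p,
    )


# ---------------------------------------------------------------------------
# LMG relative importance (exact subset enumeration)


def _subset_r2_all(covs: np.ndarray, p: int) -> np.ndarray:
    """R^2 of every predictor subset, for a stack of covariance matrices.

    ``covs`` has shape (..., p+1, p+1) with the outcome in the last row and
    column.  Returns shape (..., 2**p); entry [.., mask] is the R^2 of the
    subset encoded by the bitmask.
    """
    lead = covs.shape[:-2]
    out = np.zeros(lead + (1 << p,))
    s_yy = covs[..., p, p]
    for mask in range(1, 1 << p):
        idx = [j for j in range(p) if mask >> j & 1]
        sxx = covs[..., idx, :][..., :, idx]
        sxy = covs[..., idx, p]
        try:
            sol = np.linalg.solve(sxx, sxy[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # exactly collinear subset (e.g. duplicated predictors): use the
            # minimum-norm solution, whose fitted values are still unique
            sol = (np.linalg.pinv(sxx) @ sxy[..., None])[..., 0]
        out[..., mask] = np.einsum("...k,...k->...", sxy, sol) / s_yy
    return out


def _lmg_from_subset_r2(r2: np.ndarray, p: int) -> np.ndarray:
    """LMG shares from the full table of subset R^2 values.

    share_k = sum over subsets S not containing k of
              w(|S|) * (R^2(S + k) - R^2(S)),   w(s) = s!(p-1-s)!/p!.
    """
    w = np.array([factorial(s) * factorial(p - 1 - s) / factorial(p) for s in range(p)])
    popcount = np.array([bin(m).count("1") for m in range(1 << p)])
    shares = np.zeros(r2.shape[:-1] + (p,))
    for mask in range(1 << p):
        s = popcount[mask]
        for k in range(p):
            if mask >> k & 1:
                continue
            shares[..., k] += w[s] * (r2[..., mask | (1 << k)] - r2[..., mask])
    return shares


def lmg_shares(X: pd.DataFrame, y: pd.Series, normalized: bool = False) -> pd.Series:
    """Exact LMG decomposition of the model R^2 over the predictors.

    Enumerates all 2^p subsets, so p is capped at 20.  With
    ``normalized=True`` shares are rescaled to sum to 1 instead of R^2.
    """
    p = X.shape[1]
    if p > 20:
        raise ValueError("exact LMG enumeration is limited to 20 predictors")
    if p == 0:
        raise ValueError("need at least one predictor")
    Z = np.column_stack([X.to_numpy(dtype=float), np.asarray(y, dtype=float)])
    cov = np.cov(Z, rowvar=False, ddof=1)
    r2 = _subset_r2_all(cov, p)
    shares = _lmg_from_subset_r2(r2, p)
    if normalized:
        shares = shares / shares.sum()
    return pd.Series(shares, index=list(X.columns), name="lmg_share")


@dataclass
class ImportanceResult:
    shares: pd.Series
    r_squared: float
    contrasts: pd.DataFrame | None = None
    n_redraws: int = 0


def lmg_importance(X: pd.DataFrame, y: pd.Series, normalized: bool = False) -> ImportanceResult:
    shares = lmg_shares(X, y, normalized=normalized)
    fit = _ols(np.asarray(y, dtype=float), X)
    return ImportanceResult(shares=shares, r_squared=float(fit.rsquared))


def contrast_pairs(
    modalities: tuple[str, ...] = MODALITIES, metrics: tuple[str, ...] = METRIC_NAMES
) -> list[tuple[str, str, str, str]]:
    """(layout, label, column_a, column_b) pairs for both contrast tables.

    ``between_modalities``: same metric, modality pairs in task order.
    ``between_metrics``: same modality, metric pairs.
    """
    pairs = []
    mod_pairs = [(modalities[i], modalities[j]) for i in range(len(modalities)) for j in range(i + 1, len(modalities))]
    for met in metrics:
        for a, b in mod_pairs:
            pairs.append(("between_modalities", f"{met}: {a}-{b}", f"{a}_{met}", f"{b}_{met}"))
    met_pairs = [(metrics[i], metrics[j]) for i in range(len(metrics)) for j in range(i + 1, len(metrics))]
    for mod in modalities:
        for a, b in met_pairs:
            pairs.append(("between_metrics", f"{mod}: {a}-{b}", f"{mod}_{a}", f"{mod}_{b}"))
    return pairs


def importance_contrasts(
    X: pd.DataFrame,
    y: pd.Series,
    contrast_cols: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    normalized: bool = False,
    max_redraw: int = 100,
) -> ImportanceResult:
    """Bootstrap CIs for pairwise differences of LMG shares.

    Subjects are resampled with replacement ``n_boot`` times; a resample
    whose predictor block is numerically rank deficient is redrawn (and
    counted).  Each contrast reports the full-sample share difference and
    the percentile (1 - alpha) CI; it is flagged significant when the CI
    excludes zero.
    """
    p = X.shape[1]
    if p > 20:
        raise ValueError("exact LMG enumeration is limited to 20 predictors")
    cols = list(X.columns)
    Z = np.column_stack([X.to_numpy(dtype=float), np.asarray(y, dtype=float)])
    n = Z.shape[0]
    cov_full = np.cov(Z, rowvar=False, ddof=1)

    rng = np.random.default_rng(seed)
    covs = np.empty((n_boot, p + 1, p + 1))
    n_redraws = 0
    design_rank = np.linalg.matrix_rank(cov_full[:p, :p])
    for b in range(n_boot):
        for attempt in range(max_redraw + 1):
            idx = rng.integers(0, n, size=n)
            c = np.cov(Z[idx], rowvar=False, ddof=1)
            # a resample is degenerate when it loses rank relative to the
            # design itself (duplicated subjects collapsing a column)
            if np.linalg.matrix_rank(c[:p, :p]) >= design_rank and c[p, p] > 0:
                covs[b] = c
                break
            n_redraws += 1
        else:
            raise RuntimeError("could not draw a full-rank bootstrap resample")
    if n_redraws:
        logger.info("importance_contrasts: %d degenerate resample(s) redrawn", n_redraws)

    r2_full = _subset_r2_all(cov_full, p)
    shares_full = _lmg_from_subset_r2(r2_full, p)
    r2_boot = _subset_r2_all(covs, p)
    shares_boot = _lmg_from_subset_r2(r2_boot, p)
    if normalized:
        shares_full = shares_full / shares_full.sum()
        shares_boot = shares_boot / shares_boot.sum(axis=-1, keepdims=True)

    share_series = pd.Series(shares_full, index=cols, name="lmg_share")
    col_ix = {c: i for i, c in enumerate(cols)}
    rows = []
    for layout, label, ca, cb in contrast_pairs():
        if ca not in col_ix or cb not in col_ix:
            continue
        if contrast_cols is not None and (ca not in contrast_cols or cb not in contrast_cols):
            continue
        diff = shares_full[col_ix[ca]] - shares_full[col_ix[cb]]
        boot_diff = shares_boot[:, col_ix[ca]] - shares_boot[:, col_ix[cb]]
        lo, hi = np.percentile(boot_diff, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        rows.append(
            {
                "layout": layout,
                "contrast": label,
                "difference": float(diff),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return ImportanceResult(
        shares=share_series,
        r_squared=float(r2_full[-1]),
        contrasts=pd.DataFrame(rows),
        n_redraws=n_redraws,
    )


def behavioral_summary(subjects: pd.DataFrame) -> dict:
    """Cohort mean and range of task accuracy and response latency."""
    if subjects.empty:
        raise ValueError("empty subject table")
    return {
        "accuracy_mean": float(subjects["accuracy"].mean()),
        "accuracy_range": (
            float(subjects["accuracy"].min()),
            float(subjects["accuracy"].max()),
        ),
        "latency_mean_ms": float(subjects["latency_ms"].mean()),
        "latency_range_ms": (
            float(subjects["latency_ms"].min()),
            float(subjects["latency_ms"].max()),
        ),
    }
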