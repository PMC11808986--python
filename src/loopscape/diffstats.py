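"""Per-feature differential analysis and single-sample outlier detection.

The differential model is deliberately simple: for each feature (loop,
insulation bin, gene or peak) an ordinary-least-squares fit of

    value ~ intercept + group + covariates

with a t-test on the group coefficient and Benjamini-Hochberg FDR across
features.  A label-shuffle permutation check quantifies how many features
the pipeline calls significant under a permuted group assignment.  Cell
lines or other single samples without replicates are instead compared
against the cohort distribution with a z-score outlier test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DifferentialResult:
    feature_id: str
    beta: float
    se: float
    t: float
    p: float
    q: float
    n_used: int


@dataclass
class OutlierCall:
    feature_id: str
    sample_id: str
    z: float
    p: float
    flagged: bool
    reason: str | None = None


# ---------------------------------------------------------------------------
# expression normalization (median-of-ratios size factors)
# ---------------------------------------------------------------------------

def normalize_expression(
    counts: pd.DataFrame, min_mean_count: float = 5.0
) -> pd.DataFrame:
    """Median-of-ratios size-factor normalization of a genes x samples table.

    Genes with mean raw count below ``min_mean_count`` are removed (mean
    exactly at the threshold is retained).  Each sample's size factor is the
    median, over genes expressed in every sample, of the ratio of its count
    to the gene's geometric mean; counts are divided by the factors.
    """
    counts = counts.loc[counts.mean(axis=1) >= min_mean_count]
    arr = counts.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("size factors undefined: no gene with all-positive counts")
    ref = arr[all_positive]
    log_geo = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    return counts / size_factors


# ---------------------------------------------------------------------------
# OLS differential
# ---------------------------------------------------------------------------

def _design_matrix(
    group: pd.Series, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    g = pd.Series(group)
    if g.dtype == object or str(g.dtype) == "category":
        levels = sorted(pd.unique(g))
        if len(levels) != 2:
            raise ValueError(f"group must be binary, got levels {levels}")
        g = (g == levels[1]).astype(float)
    cols = [np.ones(len(g)), g.to_numpy(dtype=float)]
    names = ["intercept", "group"]
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype == object:
                col = pd.factorize(col)[0]
            cols.append(np.asarray(col, dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design; columns: {names}")
    return X, names


def ols_differential(
    values: pd.DataFrame,
    group: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-feature OLS of value on a binary group label plus covariates.

    ``values`` is features x samples; ``group`` and ``covariates`` are
    indexed by sample.  Returns a DataFrame (sorted stably by feature id)
    with columns beta, se, t, p, q (BH across features) and n_used.
    Features missing values are fit on their complete samples; constant
    features report beta 0, p 1.
    """
    samples = list(values.columns)
    group = pd.Series(group).loc[samples]
    if covariates is not None:
        covariates = pd.DataFrame(covariates).loc[samples]
    X_full, _ = _design_matrix(group, covariates)
    Y = values.to_numpy(dtype=float)
    n, k = X_full.shape
    complete = ~np.isnan(Y).any(axis=1)

    betas = np.empty(len(Y))
    ses = np.empty(len(Y))
    ns = np.full(len(Y), n)

    if complete.any():
        XtX_inv = np.linalg.inv(X_full.T @ X_full)
        pinv = XtX_inv @ X_full.T
        coefs = pinv @ Y[complete].T  # (k, n_features)
        resid = Y[complete].T - X_full @ coefs
        dof = n - k
        sigma2 = (resid**2).sum(axis=0) / dof
        betas[complete] = coefs[1]
        ses[complete] = np.sqrt(sigma2 * XtX_inv[1, 1])
    for idx in np.flatnonzero(~complete):
        y = Y[idx]
        ok = ~np.isnan(y)
        if ok.sum() < k + 1:
            betas[idx], ses[idx], ns[idx] = np.nan, np.nan, int(ok.sum())
            continue
        Xi = X_full[ok]
        if np.linalg.matrix_rank(Xi) < k:
            betas[idx], ses[idx], ns[idx] = np.nan, np.nan, int(ok.sum())
            continue
        XtX_inv_i = np.linalg.inv(Xi.T @ Xi)
        coef = XtX_inv_i @ Xi.T @ y[ok]
        resid = y[ok] - Xi @ coef
        sigma2 = (resid**2).sum() / (ok.sum() - k)
        betas[idx] = coef[1]
        ses[idx] = np.sqrt(sigma2 * XtX_inv_i[1, 1])
        ns[idx] = int(ok.sum())

    # constant features: OLS would divide rounding noise by rounding noise
    with np.errstate(invalid="ignore"):
        const = np.nanmax(Y, axis=1) == np.nanmin(Y, axis=1)
    betas[const], ses[const] = 0.0, 0.0

    with np.errstate(invalid="ignore", divide="ignore"):
        ts = betas / ses
    ps = np.empty(len(Y))
    for idx in range(len(Y)):
        dof = ns[idx] - k
        if not np.isfinite(ses[idx]):
            ts[idx], ps[idx] = np.nan, np.nan
        elif ses[idx] == 0:
            # zero residual variance: flat feature gets p = 1
            ts[idx] = 0.0 if betas[idx] == 0 else np.inf * np.sign(betas[idx])
            ps[idx] = 1.0 if betas[idx] == 0 else 0.0
        else:
            ps[idx] = 2 * stats.t.sf(abs(ts[idx]), dof)

    out = pd.DataFrame(
        {
            "feature_id": values.index,
            "beta": betas,
            "se": ses,
            "t": ts,
            "p": ps,
            "n_used": ns,
        }
    ).sort_values("feature_id", kind="mergesort").reset_index(drop=True)
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    return out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def permutation_null_check(
    values: pd.DataFrame,
    group: pd.Series,
    covariates: pd.DataFrame | None,
    n_shuffles: int,
    fdr_threshold: float = 0.1,
    seed: int = 0,
) -> list[int]:
    """Label-shuffle null: re-run the differential pipeline on permuted labels.

    Group labels are permuted across samples (covariates stay attached to
    their samples); returns the number of features with q below
    ``fdr_threshold`` for each shuffle.
    """
    rng = np.random.default_rng(seed)
    group = pd.Series(group).loc[values.columns]
    counts = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(group))
        shuffled = pd.Series(group.to_numpy()[perm], index=group.index)
        res = ols_differential(values, shuffled, covariates)
        counts.append(int((res["q"] < fdr_threshold).sum()))
    return counts


# ---------------------------------------------------------------------------
# single-sample outlier test
# ---------------------------------------------------------------------------

def single_sample_outlier(
    cohort_values: np.ndarray,
    query_value: float,
    feature_id: str = "",
    sample_id: str = "",
    alpha: float = 0.05,
) -> OutlierCall:
    """z-score of a single query sample against the cohort distribution.

    z = (query - cohort mean) / cohort sd; p is the two-sided standard-normal
    tail; flagged iff p < ``alpha`` (strict).  Requires >= 3 finite cohort
    values with positive spread.
    """
    vals = np.asarray(cohort_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 3:
        return OutlierCall(feature_id, sample_id, np.nan, np.nan, False,
                           reason="fewer than 3 cohort values")
    sd = vals.std(ddof=1)
    if sd == 0:
        return OutlierCall(feature_id, sample_id, np.nan, np.nan, False,
                           reason="degenerate cohort")
    z = (query_value - vals.mean()) / sd
    p = 2 * stats.norm.sf(abs(z))
    return OutlierCall(feature_id, sample_id, float(z), float(p), bool(p < alpha))


def cohort_outlier_scan(
    cohort: pd.DataFrame, query: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Outlier calls for one query sample over all features of a cohort table."""
    rows = []
    for fid in cohort.index:
        call = single_sample_outlier(
            cohort.loc[fid].to_numpy(), query.get(fid, np.nan),
            feature_id=str(fid), sample_id=str(query.name or "query"), alpha=alpha,
        )
        rows.append(call.__dict__)
    return pd.DataFrame(rows)
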