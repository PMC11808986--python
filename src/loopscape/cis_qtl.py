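"""Cis-QTL mapping with permutation-calibrated adjusted p-values.

Any molecular phenotype (expression, accessibility, insulation, loop
strength) is tested against all variants within a 1 Mb cis window of its
interval using least squares with covariates.  Phenotype-level significance
is calibrated by permuting the phenotype across samples (genotypes and
covariates fixed), recording the minimum nominal p per permutation, fitting
a Beta(a, b) distribution to the permutation minima by maximum likelihood
and evaluating its CDF at the observed lead p.  BH FDR is then applied
across phenotypes (FDR < 0.1 defines the significant set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomicInterval, GenotypeMatrix
from .diffstats import bh_fdr


@dataclass
class QTLResult:
    phenotype_id: str
    lead_variant: str
    slope: float
    p_nominal: float
    p_adjusted: float
    p_empirical: float
    n_variants_tested: int
    beta_shape1: float
    beta_shape2: float
    beta_fit_ok: bool
    q: float = np.nan


# ---------------------------------------------------------------------------
# transforms and sample QC
# ---------------------------------------------------------------------------

def rank_normal_transform(values: np.ndarray) -> np.ndarray:
    """Map values to normal quantiles: value_i -> Phi^-1((rank_i - 0.5) / n).

    Average ranks for ties; all-tied input maps to zeros with a warning.
    Missing values stay missing and do not consume ranks.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    n = ok.sum()
    if n < 3:
        raise ValueError("rank-normal transform needs >= 3 non-missing values")
    if np.ptp(v[ok]) == 0:
        warnings.warn("all values tied; rank-normal transform maps them to 0")
        out[ok] = 0.0
        return out
    ranks = stats.rankdata(v[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def pca_sample_qc(
    values: pd.DataFrame, n_pcs: int = 3, sd_threshold: float = 3.0
) -> tuple[list[str], pd.DataFrame]:
    """Remove PCA-outlier samples and return PC covariates for the rest.

    Samples beyond ``sd_threshold`` standard deviations from the mean on
    either of the first two PCs are dropped; the first ``n_pcs`` PCs are then
    recomputed on the retained samples and returned as covariates.
    """
    samples = list(values.columns)
    if len(samples) < 5:
        raise ValueError("PCA sample QC needs >= 5 samples")
    if n_pcs >= len(samples):
        raise ValueError("n_pcs must be smaller than the number of samples")

    def _scores(cols: list[str], k: int) -> np.ndarray:
        X = values[cols].to_numpy(dtype=float).T  # samples x features
        X = X - X.mean(axis=0)
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        return X @ vt[:k].T

    scores = _scores(samples, 2)
    keep_mask = np.ones(len(samples), dtype=bool)
    for pc in range(scores.shape[1]):
        col = scores[:, pc]
        sd = col.std(ddof=1)
        if sd > 0:
            keep_mask &= np.abs(col - col.mean()) <= sd_threshold * sd
    retained = [s for s, k in zip(samples, keep_mask) if k]
    pcs = _scores(retained, n_pcs)
    pc_table = pd.DataFrame(
        pcs, index=retained, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )
    return retained, pc_table


# ---------------------------------------------------------------------------
# association internals
# ---------------------------------------------------------------------------

def _residualize(M: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Project out an intercept and covariate columns from each column of M."""
    n = M.shape[0]
    X = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef


def _corr_to_p(r: np.ndarray, dof: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    p = 2 * stats.t.sf(np.abs(t), dof)
    return np.where(np.isfinite(t), p, 0.0)


def _cis_variant_mask(
    genotypes: GenotypeMatrix, interval: GenomicInterval, window: int
) -> np.ndarray:
    v = genotypes.variants
    return (
        (v["chrom"] == interval.chrom)
        & (v["pos"] >= interval.start - window)
        & (v["pos"] < interval.end + window)
    ).to_numpy()


def nominal_cis_scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    intervals: dict[str, GenomicInterval],
    covariates: pd.DataFrame | None = None,
    window: int = 1_000_000,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Slope and p for every (variant, phenotype) pair within the cis window.

    ``phenotypes`` is features x samples (already transformed for the
    modality); ``intervals`` maps feature id to its cis anchor interval
    (gene TSS point, peak interval, insulation bin, loop span).  Samples
    with missing dosage are excluded pairwise; monomorphic pairs and pairs
    with fewer than ``min_samples`` usable samples are skipped.
    """
    samples = list(phenotypes.columns)
    order = [genotypes.samples.index(s) for s in samples]
    G = genotypes.dosages[:, order].T  # samples x variants
    C = covariates.loc[samples].to_numpy(dtype=float) if covariates is not None else None
    n_cov = 0 if C is None else C.shape[1]
    rows = []
    for fid in phenotypes.index:
        interval = intervals[fid]
        mask = _cis_variant_mask(genotypes, interval, window)
        if not mask.any():
            continue
        y = phenotypes.loc[fid].to_numpy(dtype=float)
        for vi in np.flatnonzero(mask):
            g = G[:, vi]
            ok = np.isfinite(g) & np.isfinite(y)
            if ok.sum() < min_samples:
                continue
            if np.ptp(g[ok]) == 0:
                continue  # monomorphic after missing-data removal
            slope, se, p = _single_assoc(g[ok], y[ok], None if C is None else C[ok])
            rows.append(
                {
                    "phenotype_id": fid,
                    "variant_id": genotypes.variants["id"][vi],
                    "slope": slope,
                    "se": se,
                    "p": p,
                    "n": int(ok.sum()),
                }
            )
    return pd.DataFrame(
        rows, columns=["phenotype_id", "variant_id", "slope", "se", "p", "n"]
    )


def _single_assoc(
    g: np.ndarray, y: np.ndarray, C: np.ndarray | None
) -> tuple[float, float, float]:
    n = len(g)
    X = np.column_stack(
        [np.ones(n), g] if C is None else [np.ones(n), g, C]
    )
    k = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ y
    resid = y - X @ coef
    dof = n - k
    sigma2 = (resid**2).sum() / dof
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    if se == 0:
        return float(coef[1]), se, 1.0
    t = coef[1] / se
    return float(coef[1]), se, float(2 * stats.t.sf(abs(t), dof))


# ---------------------------------------------------------------------------
# permutation pass with beta approximation
# ---------------------------------------------------------------------------

def fit_beta_mle(x: np.ndarray) -> tuple[float, float, bool]:
    """Maximum-likelihood Beta(a, b) fit on (0, 1) data; ok flag on convergence."""
    x = np.clip(np.asarray(x, dtype=float), 1e-12, 1 - 1e-12)
    try:
        a, b, _, _ = stats.beta.fit(x, floc=0, fscale=1)
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            return np.nan, np.nan, False
        return float(a), float(b), True
    except Exception:
        return np.nan, np.nan, False


def permutation_adjusted_pvalues(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    interval: GenomicInterval,
    covariates: pd.DataFrame | None = None,
    window: int = 1_000_000,
    n_perm: int = 1000,
    seed: int = 0,
    min_samples: int = 10,
) -> QTLResult | None:
    """Phenotype-level adjusted p via a permutation pass with a beta fit.

    The lead association is the minimum nominal p over cis variants.  Each
    permutation shuffles the phenotype across samples (genotypes and
    covariates fixed) and records the minimum p; a Beta(a, b) fitted by MLE
    to the permutation minima gives adjusted p = BetaCDF(observed lead p).
    Falls back to the empirical permutation p, flagged, when the beta fit
    does not converge.  Returns None when no cis variant is testable.
    """
    rng = np.random.default_rng(seed)
    samples = list(phenotype.index)
    order = [genotypes.samples.index(s) for s in samples]
    mask = _cis_variant_mask(genotypes, interval, window)
    if not mask.any():
        return None
    G = genotypes.dosages[np.flatnonzero(mask)][:, order].T  # samples x cis variants
    var_ids = genotypes.variants["id"].to_numpy()[mask]
    y = phenotype.to_numpy(dtype=float)
    ok_y = np.isfinite(y)
    y = y[ok_y]
    G = G[ok_y]
    C = (
        covariates.loc[np.array(samples)[ok_y]].to_numpy(dtype=float)
        if covariates is not None
        else None
    )
    n = len(y)
    n_cov = 0 if C is None else C.shape[1]
    dof = n - 2 - n_cov

    usable = []
    for vi in range(G.shape[1]):
        g = G[:, vi]
        fin = np.isfinite(g)
        if fin.sum() >= min_samples and np.ptp(g[fin]) > 0:
            usable.append(vi)
    if not usable:
        return None

    # observed scan (slope on the original scale, exact pairwise exclusion)
    best_p, best_vi, best_slope = np.inf, None, np.nan
    for vi in usable:
        g = G[:, vi]
        fin = np.isfinite(g)
        slope, _, p = _single_assoc(g[fin], y[fin], None if C is None else C[fin])
        if p < best_p:
            best_p, best_vi, best_slope = p, vi, slope

    # permutation minima (vectorized; complete-dosage variants share the fast path)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)]).T  # n x n_perm
    Y_perm = _residualize(y[perm_idx], C)
    Y_perm /= np.linalg.norm(Y_perm, axis=0, keepdims=True)
    minima = np.ones(n_perm)
    complete = [vi for vi in usable if np.isfinite(G[:, vi]).all()]
    partial = [vi for vi in usable if vi not in complete]
    if complete:
        Gc = _residualize(G[:, complete], C)
        norms = np.linalg.norm(Gc, axis=0, keepdims=True)
        Gc = Gc / norms
        r = Gc.T @ Y_perm  # variants x perms
        p = _corr_to_p(r, dof)
        minima = np.minimum(minima, p.min(axis=0))
    for vi in partial:
        g = G[:, vi]
        fin = np.isfinite(g)
        gr = _residualize(g[fin, None], None if C is None else C[fin])
        gr /= np.linalg.norm(gr)
        yr = _residualize(y[perm_idx][fin], None if C is None else C[fin])
        yr /= np.linalg.norm(yr, axis=0, keepdims=True)
        r = (gr.T @ yr).ravel()
        p = _corr_to_p(r, int(fin.sum()) - 2 - n_cov)
        minima = np.minimum(minima, p)

    a, b, ok = fit_beta_mle(minima)
    p_emp = float((1 + (minima <= best_p).sum()) / (n_perm + 1))
    p_adj = float(stats.beta.cdf(best_p, a, b)) if ok else p_emp
    return QTLResult(
        phenotype_id=str(phenotype.name),
        lead_variant=str(var_ids[best_vi]),
        slope=float(best_slope),
        p_nominal=float(best_p),
        p_adjusted=p_adj,
        p_empirical=p_emp,
        n_variants_tested=len(usable),
        beta_shape1=a,
        beta_shape2=b,
        beta_fit_ok=ok,
    )


def map_qtls(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    intervals: dict[str, GenomicInterval],
    covariates: pd.DataFrame | None = None,
    window: int = 1_000_000,
    n_perm: int = 1000,
    seed: int = 0,
    rank_normal: bool = True,
) -> pd.DataFrame:
    """Permutation pass over all phenotypes, then BH FDR across phenotypes.

    The rank-normal transform is applied per phenotype after the modality
    transform (matching the permutation software's ``--normal`` behaviour)
    unless disabled.
    """
    rng = np.random.default_rng(seed)
    results = []
    for fid in phenotypes.index:
        y = phenotypes.loc[fid]
        if rank_normal:
            y = pd.Series(rank_normal_transform(y.to_numpy()), index=y.index, name=fid)
        res = permutation_adjusted_pvalues(
            genotypes, y, intervals[fid], covariates,
            window=window, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)),
        )
        if res is not None:
            results.append(res)
    return qtl_fdr(results)


def qtl_fdr(results: list[QTLResult], fdr: float = 0.1) -> pd.DataFrame:
    """BH correction of adjusted p across phenotypes; q < ``fdr`` is significant."""
    if not results:
        return pd.DataFrame(
            columns=["phenotype_id", "lead_variant", "slope", "p_nominal",
                     "p_adjusted", "q", "significant", "n_variants_tested",
                     "beta_shape1", "beta_shape2", "beta_fit_ok"]
        )
    df = pd.DataFrame([r.__dict__ for r in results])
    df["q"] = bh_fdr(df["p_adjusted"].to_numpy())
    df["significant"] = df["q"] < fdr
    cols = ["phenotype_id", "lead_variant", "slope", "p_nominal", "p_adjusted",
            "p_empirical", "q", "significant", "n_variants_tested",
            "beta_shape1", "beta_shape2", "beta_fit_ok"]
    return df[cols]


def cross_qtl_concordance(
    reference: pd.DataFrame,
    other_nominal: pd.DataFrame,
    p_threshold: float = 1e-2,
) -> dict[str, float]:
    """Replication of significant lead pairs in a second condition's nominal scan.

    ``overlap`` is the fraction of reference (phenotype, lead variant) pairs
    found in the other condition at nominal p below ``p_threshold``;
    ``sign_concordance`` the fraction of those with the same slope sign.
    Empty reference yields NaN fractions.
    """
    ref = reference[reference.get("significant", True) == True]  # noqa: E712
    if len(ref) == 0:
        return {"overlap": np.nan, "sign_concordance": np.nan, "n_reference": 0,
                "n_overlap": 0}
    other = other_nominal.set_index(["phenotype_id", "variant_id"])
    n_overlap = 0
    n_sign = 0
    for row in ref.itertuples(index=False):
        key = (row.phenotype_id, row.lead_variant)
        if key not in other.index:
            continue
        hit = other.loc[key]
        if float(hit["p"]) < p_threshold:
            n_overlap += 1
            if np.sign(hit["slope"]) == np.sign(row.slope):
                n_sign += 1
    return {
        "overlap": n_overlap / len(ref),
        "sign_concordance": (n_sign / n_overlap) if n_overlap else np.nan,
        "n_reference": int(len(ref)),
        "n_overlap": n_overlap,
    }
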