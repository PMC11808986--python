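"""Chromatin-conformation phenotypes from contact matrices.

Two phenotypes are produced per sample and chromosome:

* **loop strength** — the sum of balanced contacts in a 15x15 kb (3x3 pixel)
  window centred on the pixel containing the loop anchors' midpoints, at 5 kb
  resolution, normalised across libraries by the ratio of expected
  distance-decay curves against a reference library;
* **insulation score** — log2 of the mean balanced contact in a sliding
  diamond (100 kb window at 25 kb bins) crossing each bin, relative to the
  chromosome-wide mean diamond, then quantile-normalised across libraries.

Matrix balancing is iterative correction (ICE): bin weights are iterated
until every unmasked bin's weighted marginal equals the mean marginal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import ContactMatrix, Loop


@dataclass
class DecayProfile:
    """Expected balanced contact count per genomic-distance lag, one chromosome.

    ``expected[k]`` is the mean balanced count over all unmasked pixel pairs
    whose genomic distance falls in lag bin ``k`` of width ``lag_resolution``
    (default 10 kb).  Lags with no unmasked pixels are NaN, never 0.
    """

    chrom: str
    lag_resolution: int
    expected: np.ndarray

    def at_distance(self, distance: int) -> float:
        """E(d) at the lag nearest ``distance``; NaN if outside the profile."""
        lag = int(round(distance / self.lag_resolution))
        if lag < 0 or lag >= len(self.expected):
            return np.nan
        return float(self.expected[lag])


@dataclass
class LoopCountMatrix:
    """Loops x samples strengths with a provenance flag.

    ``normalization`` is one of ``raw``, ``decay_normalized``, ``log2``; log2
    is only applied after decay normalization.
    """

    loops: list[Loop]
    strengths: pd.DataFrame  # index loop ids, columns sample ids
    normalization: str = "raw"
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        if len(self.loops) != len(self.strengths):
            raise ValueError("loops / strengths dimensions inconsistent")

    def log2(self, pseudocount: float = 1.0) -> "LoopCountMatrix":
        if self.normalization != "decay_normalized":
            raise ValueError("log2 transform requires decay-normalized strengths")
        return LoopCountMatrix(
            self.loops,
            np.log2(self.strengths + pseudocount),
            normalization="log2",
            reference_sample=self.reference_sample,
        )


@dataclass
class InsulationTrack:
    """Insulation scores per bin and sample; NaN within a window of the edges."""

    chrom: str
    bin_size: int
    window: int
    scores: pd.DataFrame  # index bin index, columns sample ids
    normalization: str = "raw"


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

def balance_matrix(
    raw: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ContactMatrix:
    """Iterative-correction balancing.

    Multiplies counts by per-bin weights ``w_i w_j`` so that every unmasked
    bin's marginal equals the mean marginal, to relative tolerance ``tol``.
    Bins with zero raw coverage are masked (NaN weight) and excluded from all
    downstream windows.
    """
    coo = raw.counts.tocoo()
    if coo.nnz == 0 or coo.data.sum() == 0:
        raise ValueError("nothing to balance: all-zero matrix")
    n = raw.n_bins
    full = sp.coo_matrix(
        (
            np.concatenate([coo.data, coo.data[coo.row != coo.col]]),
            (
                np.concatenate([coo.row, coo.col[coo.row != coo.col]]),
                np.concatenate([coo.col, coo.row[coo.row != coo.col]]),
            ),
        ),
        shape=(n, n),
    ).tocsr()
    coverage = np.asarray(full.sum(axis=1)).ravel()
    masked = coverage == 0
    w = np.ones(n)
    w[masked] = 0.0
    for _ in range(max_iter):
        marg = np.asarray(full @ w).ravel() * w
        active = marg[~masked]
        mean_marg = active.mean()
        if mean_marg == 0:
            raise ValueError("nothing to balance: zero marginals on unmasked bins")
        rel = np.abs(active / mean_marg - 1.0)
        if rel.max() < tol:
            break
        scale = np.ones(n)
        nonzero = ~masked & (marg > 0)
        scale[nonzero] = np.sqrt(marg[nonzero] / mean_marg)
        w[nonzero] /= scale[nonzero]
    # normalize so the mean unmasked weight is 1 (scale is arbitrary)
    w[~masked] /= w[~masked].mean()
    weights = w.copy()
    weights[masked] = np.nan
    return ContactMatrix(
        chrom=raw.chrom,
        resolution=raw.resolution,
        n_bins=n,
        counts=raw.counts.copy(),
        balance_weights=weights,
        masked_bins=frozenset(np.flatnonzero(masked).tolist()),
    )


def _balanced_dense(matrix: ContactMatrix) -> np.ndarray:
    """Dense symmetric balanced matrix with NaN on masked rows/cols."""
    if not matrix.is_balanced:
        raise ValueError("matrix must be balanced")
    return matrix.to_dense(balanced=True)


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

def expected_cis_decay(
    matrix: ContactMatrix, lag_resolution: int = 10_000
) -> DecayProfile:
    """Expected balanced count per genomic-distance lag (default 10 kb lags).

    E(d) is the mean over all unmasked pixel pairs (including zero pixels) at
    each lag; lags with no unmasked pixels are NaN.
    """
    if lag_resolution % matrix.resolution != 0:
        raise ValueError(
            f"lag_resolution {lag_resolution} is not a multiple of the matrix "
            f"resolution {matrix.resolution}"
        )
    dense = _balanced_dense(matrix)
    n = matrix.n_bins
    bins_per_lag = lag_resolution // matrix.resolution
    n_lags = (n - 1) // bins_per_lag + 1
    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags)
    for sep in range(n):
        diag = np.diagonal(dense, offset=sep)
        ok = np.isfinite(diag)
        lag = sep // bins_per_lag
        sums[lag] += diag[ok].sum()
        counts[lag] += ok.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = np.where(counts > 0, sums / counts, np.nan)
    return DecayProfile(
        chrom=matrix.chrom, lag_resolution=lag_resolution, expected=expected
    )


# ---------------------------------------------------------------------------
# loop strengths
# ---------------------------------------------------------------------------

def extract_loop_counts(
    matrix: ContactMatrix,
    loops: list[Loop],
    block: int = 3,
    aggregate: str = "sum",
) -> np.ndarray:
    """Balanced contact strength per loop from a 3x3 pixel window.

    The window is centred on the pixel containing (mid(anchor1),
    mid(anchor2)) and spans ``block`` pixels a side (3 pixels = 15 kb at the
    expected 5 kb resolution), clipped at the matrix bounds.  Masked pixels
    contribute 0.  ``aggregate`` is ``sum`` (default) or ``mean``.
    """
    dense = _balanced_dense(matrix)
    dense = np.nan_to_num(dense, nan=0.0)
    half = block // 2
    n = matrix.n_bins
    out = np.zeros(len(loops))
    for k, loop in enumerate(loops):
        if loop.chrom != matrix.chrom:
            raise ValueError(
                f"loop {loop.id} on {loop.chrom}, matrix holds {matrix.chrom}"
            )
        ci = loop.anchor1.midpoint // matrix.resolution
        cj = loop.anchor2.midpoint // matrix.resolution
        if ci >= n or cj >= n:
            raise ValueError(f"loop {loop.id} beyond matrix bounds")
        i0, i1 = max(0, ci - half), min(n, ci + half + 1)
        j0, j1 = max(0, cj - half), min(n, cj + half + 1)
        window = dense[i0:i1, j0:j1]
        out[k] = window.sum() if aggregate == "sum" else window.mean()
    return out


def decay_normalize_counts(
    strengths: np.ndarray,
    loops: list[Loop],
    sample_decay: DecayProfile,
    reference_decay: DecayProfile,
) -> np.ndarray:
    """Cross-library normalization by the decay-curve ratio at each loop's distance.

    ``normalized = raw * E_ref(d) / E_sample(d)`` with d the loop midpoint
    distance rounded to the nearest lag.  Where E_sample(d) is 0 or undefined
    the strength is NaN (missing), never 0.
    """
    out = np.empty(len(loops))
    for k, loop in enumerate(loops):
        d = loop.midpoint_distance
        e_s = sample_decay.at_distance(d)
        e_r = reference_decay.at_distance(d)
        if not np.isfinite(e_s) or e_s == 0 or not np.isfinite(e_r):
            out[k] = np.nan
        else:
            out[k] = strengths[k] * e_r / e_s
    return out


def quantify_loops(
    matrices: dict[str, ContactMatrix],
    loops: list[Loop],
    reference_sample: str | None = None,
    lag_resolution: int = 10_000,
    log2: bool = False,
) -> LoopCountMatrix:
    """End-to-end per-sample loop strengths: balance, extract, decay-normalize.

    ``matrices`` maps sample id to a raw or balanced contact matrix of one
    chromosome.  The reference library for decay normalization defaults to
    the lexicographically first sample.
    """
    samples = sorted(matrices)
    if reference_sample is None:
        reference_sample = samples[0]
    balanced = {
        s: (m if m.is_balanced else balance_matrix(m)) for s, m in matrices.items()
    }
    decays = {s: expected_cis_decay(m, lag_resolution) for s, m in balanced.items()}
    ref_decay = decays[reference_sample]
    cols = {}
    for s in samples:
        raw = extract_loop_counts(balanced[s], loops)
        cols[s] = decay_normalize_counts(raw, loops, decays[s], ref_decay)
    table = pd.DataFrame(cols, index=[lp.id for lp in loops])
    lcm = LoopCountMatrix(
        loops, table, normalization="decay_normalized", reference_sample=reference_sample
    )
    return lcm.log2() if log2 else lcm


# ---------------------------------------------------------------------------
# insulation
# ---------------------------------------------------------------------------

def insulation_score(
    matrix: ContactMatrix, bin_size: int = 25_000, window: int = 100_000
) -> np.ndarray:
    """Diamond insulation score per bin; NaN within ``window`` of either edge.

    For interior bin i and w = window/bin_size, the diamond is the block of
    pixels rows [i-w, i-1] x columns [i+1, i+w] (the diagonal pixel (i, i) is
    excluded by construction).  The score is log2 of the mean balanced count
    over unmasked pixels of the diamond, divided by the chromosome-wide mean
    of those diamond means.
    """
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    if bin_size % matrix.resolution != 0:
        raise ValueError("bin_size must be a multiple of the matrix resolution")
    dense = _balanced_dense(matrix)
    agg = bin_size // matrix.resolution
    if agg > 1:
        n_coarse = matrix.n_bins // agg
        trimmed = dense[: n_coarse * agg, : n_coarse * agg]
        resh = trimmed.reshape(n_coarse, agg, n_coarse, agg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dense = np.nanmean(resh, axis=(1, 3))
    n = dense.shape[0]
    w = window // bin_size
    if n < 2 * w + 1:
        warnings.warn(
            f"{matrix.chrom}: chromosome shorter than twice the window; "
            "insulation undefined everywhere"
        )
        return np.full(n, np.nan)
    means = np.full(n, np.nan)
    for i in range(w, n - w):
        block = dense[i - w : i, i + 1 : i + w + 1]
        finite = block[np.isfinite(block)]
        if finite.size:
            means[i] = finite.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        chrom_mean = np.nanmean(means)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2(means / chrom_mean)


def insulation_track(
    matrices: dict[str, ContactMatrix],
    bin_size: int = 25_000,
    window: int = 100_000,
    quantile_normalized: bool = True,
) -> InsulationTrack:
    """Per-sample insulation scores, optionally quantile-normalized across libraries."""
    samples = sorted(matrices)
    balanced = {
        s: (m if m.is_balanced else balance_matrix(m)) for s, m in matrices.items()
    }
    cols = {s: insulation_score(balanced[s], bin_size, window) for s in samples}
    scores = pd.DataFrame(cols)
    chrom = next(iter(matrices.values())).chrom
    if quantile_normalized:
        scores = quantile_normalize(scores)
        norm = "quantile"
    else:
        norm = "raw"
    return InsulationTrack(
        chrom=chrom, bin_size=bin_size, window=window, scores=scores, normalization=norm
    )


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Map every sample (column) onto the cross-sample mean quantile vector.

    After normalization each sample's sorted non-missing values equal the
    mean of the per-sample sorted vectors; within-sample ranks are preserved
    and ties receive the mean of their tied reference values.  Samples with
    fewer than 2 non-missing values are excluded with a warning.  Missing
    entries stay missing.
    """
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    usable = [c for c in values.columns if values[c].notna().sum() >= 2]
    dropped = [c for c in values.columns if c not in usable]
    if dropped:
        warnings.warn(f"excluded samples with <2 non-missing values: {dropped}")
    sub = values[usable]
    n = len(sub)
    grid = (np.arange(n) + 0.5) / n
    sorted_interp = []
    for c in usable:
        col = sub[c].dropna().sort_values().to_numpy()
        q = (np.arange(col.size) + 0.5) / col.size
        sorted_interp.append(np.interp(grid, q, col))
    reference = np.mean(sorted_interp, axis=0)
    out = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
    for c in usable:
        col = sub[c]
        mask = col.notna()
        vals = col[mask].to_numpy()
        k = vals.size
        ref_k = (
            reference
            if k == n
            else np.interp((np.arange(k) + 0.5) / k, grid, reference)
        )
        order = np.argsort(vals, kind="mergesort")
        mapped = np.empty(k)
        mapped[order] = ref_k
        # ties -> mean of tied reference values
        ser = pd.Series(mapped)
        tied = pd.Series(vals)
        mapped = ser.groupby(tied.values).transform("mean").to_numpy()
        out.loc[mask, c] = mapped
    return out
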