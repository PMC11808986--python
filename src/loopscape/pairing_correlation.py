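"""Correlation of loop strengths with expression/accessibility by positional class.

Each (loop, feature) pair on a chromosome is assigned one of four mutually
exclusive positional classes relative to the loop:

* ``anchor_overlap`` — the feature point (TSS or peak midpoint) lies inside
  an anchor;
* ``spanned`` — the point lies strictly between the anchors;
* ``nearby`` — outside the span but within 250 kb of the nearest loop end;
* ``distal`` — more than 250 kb but at most 4 Mb away (the background set).

Pairs beyond 4 Mb are not classified.  Pearson correlation across samples is
then computed for pairs passing expression/strength/accessibility filters,
optionally restricted to loops differential between cell types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Loop
from .hic_quant import InsulationTrack

NEARBY_MAX = 250_000
BACKGROUND_MAX = 4_000_000


@dataclass
class CorrelationRecord:
    loop_id: str
    feature_id: str
    pair_class: str | None
    r: float
    p: float
    n: int


def classify_loop_feature_pair(
    loop: Loop,
    feature_point: int,
    feature_chrom: str | None = None,
    nearby_max: int = NEARBY_MAX,
    background_max: int = BACKGROUND_MAX,
) -> str | None:
    """Positional class of a feature point relative to a loop; None if out of range."""
    if feature_chrom is not None and feature_chrom != loop.chrom:
        return None
    p = feature_point
    if loop.anchor1.contains(p) or loop.anchor2.contains(p):
        return "anchor_overlap"
    if loop.anchor1.end <= p < loop.anchor2.start:
        return "spanned"
    if p < loop.anchor1.start:
        dist = loop.anchor1.start - p
    elif p >= loop.anchor2.end:
        dist = p - loop.anchor2.end + 1
    else:
        # inside an anchor was handled above; remaining points are boundary-exact
        dist = 0
    if dist > background_max:
        return None
    return "nearby" if dist <= nearby_max else "distal"


@dataclass
class PairFilters:
    """Mean-signal filters applied before correlating a pair.

    Genes must be expressed (mean count > 5), loops must have a mean
    interaction strength of at least 10 and peaks a mean accessibility of at
    least 10 reads; loops may additionally be restricted to a differential
    set (FDR < 0.01 between cell types).
    """

    gene_mean_min: float = 5.0  # strict >
    loop_mean_min: float = 10.0  # >=
    peak_mean_min: float = 10.0  # >=
    min_samples: int = 3


def correlate_loop_feature(
    loop_strengths: pd.Series,
    feature_values: pd.Series,
    loop_id: str = "",
    feature_id: str = "",
    feature_kind: str = "gene",
    pair_class: str | None = None,
    filters: PairFilters | None = None,
) -> CorrelationRecord | tuple[None, str]:
    """Pearson correlation of one loop's strength with one feature across samples.

    Returns a :class:`CorrelationRecord`, or ``(None, reason)`` when the
    pair fails a filter or has zero variance.
    """
    filters = filters or PairFilters()
    joined = pd.concat([loop_strengths, feature_values], axis=1, join="inner").dropna()
    if len(joined) < filters.min_samples:
        return None, "fewer than 3 paired samples"
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if x.mean() < filters.loop_mean_min:
        return None, "loop mean strength below threshold"
    if feature_kind == "gene" and not (y.mean() > filters.gene_mean_min):
        return None, "gene mean count below threshold"
    if feature_kind == "peak" and y.mean() < filters.peak_mean_min:
        return None, "peak mean accessibility below threshold"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, "zero variance"
    r, p = stats.pearsonr(x, y)
    return CorrelationRecord(loop_id, feature_id, pair_class, float(r), float(p), len(joined))


def correlate_loops_with_features(
    strengths: pd.DataFrame,
    loops: list[Loop],
    feature_values: pd.DataFrame,
    feature_points: dict[str, int],
    feature_kind: str = "gene",
    differential_loops: set[str] | None = None,
    filters: PairFilters | None = None,
    nearby_max: int = NEARBY_MAX,
    background_max: int = BACKGROUND_MAX,
) -> pd.DataFrame:
    """All classified (loop, feature) correlations on one chromosome.

    ``feature_points`` maps feature id to its anchor position (TSS for
    genes, midpoint for peaks).  When ``differential_loops`` is given, only
    those loops are tested (the paper restricts to loops differential
    between cell types at FDR < 0.01).
    """
    rows = []
    loop_by_id = {lp.id: lp for lp in loops}
    for loop_id, loop in loop_by_id.items():
        if differential_loops is not None and loop_id not in differential_loops:
            continue
        if loop_id not in strengths.index:
            continue
        for fid, point in feature_points.items():
            if fid not in feature_values.index:
                continue
            cls = classify_loop_feature_pair(
                loop, point, nearby_max=nearby_max, background_max=background_max
            )
            if cls is None:
                continue
            rec = correlate_loop_feature(
                strengths.loc[loop_id],
                feature_values.loc[fid],
                loop_id=loop_id,
                feature_id=fid,
                feature_kind=feature_kind,
                pair_class=cls,
                filters=filters,
            )
            if isinstance(rec, CorrelationRecord):
                rows.append(rec.__dict__)
    return pd.DataFrame(
        rows, columns=["loop_id", "feature_id", "pair_class", "r", "p", "n"]
    )


def insulation_expression_correlation(
    de_genes: list[str],
    insulation: InsulationTrack,
    expression: pd.DataFrame,
    tss: dict[str, int],
) -> pd.DataFrame:
    """Correlate each differential gene's expression with its promoter bin's insulation.

    The promoter bin is the insulation bin containing the TSS; genes whose
    TSS falls in an undefined (edge) bin are excluded with a reason.
    Returns one row per gene with r, p, n or an exclusion reason.
    """
    rows = []
    samples = [s for s in expression.columns if s in insulation.scores.columns]
    for gid in de_genes:
        if gid not in expression.index or gid not in tss:
            rows.append({"gene_id": gid, "r": np.nan, "p": np.nan, "n": 0,
                         "reason": "gene missing"})
            continue
        bin_idx = tss[gid] // insulation.bin_size
        if bin_idx not in insulation.scores.index:
            rows.append({"gene_id": gid, "r": np.nan, "p": np.nan, "n": 0,
                         "reason": "TSS outside track"})
            continue
        ins = insulation.scores.loc[bin_idx, samples]
        expr = expression.loc[gid, samples]
        joined = pd.concat([ins, expr], axis=1).dropna()
        if len(joined) < 3:
            rows.append({"gene_id": gid, "r": np.nan, "p": np.nan, "n": len(joined),
                         "reason": "undefined promoter bin"})
            continue
        x = joined.iloc[:, 0].to_numpy(dtype=float)
        y = joined.iloc[:, 1].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"gene_id": gid, "r": np.nan, "p": np.nan, "n": len(joined),
                         "reason": "zero variance"})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"gene_id": gid, "r": float(r), "p": float(p), "n": len(joined),
                     "reason": None})
    return pd.DataFrame(rows, columns=["gene_id", "r", "p", "n", "reason"])
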