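"""Exon-level mark summaries and differential-expression classification.

Exon-array log2 intensities are inputs here (array preprocessing happens
upstream).  Exons are stratified into high / low / mid expression by
empirical quantiles (default: top and bottom 15%), mark signals are
summarised over first/last exons, introns and first/last coding exons in
transcriptional orientation, and genes are called up/down regulated between
two conditions by a plain |delta log2| threshold (default 0.5, inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnalysisParams, GeneModel, Region
from .occupancy_stats import CorrelationResult, pearson_correlation
from .signal_io import SignalTrack, assign_probe_values

__all__ = [
    "StrataAssignment",
    "select_expression_extremes",
    "exon_intron_summary",
    "coding_exon_summary",
    "classify_differential",
    "ExpressionCpgResult",
    "expression_change_vs_cpg",
    "boxplot_stats",
]


@dataclass(frozen=True)
class StrataAssignment:
    """Expression strata over exons (or genes).

    ``strata`` holds "high" / "low" / "mid" per id.  ``degenerate`` is set
    when the two quantile thresholds collapse (e.g. all intensities equal);
    no extreme strata are assigned in that case.
    """

    strata: pd.Series
    degenerate: bool
    low_threshold: float
    high_threshold: float

    @property
    def high(self) -> pd.Index:
        return self.strata.index[self.strata == "high"]

    @property
    def low(self) -> pd.Index:
        return self.strata.index[self.strata == "low"]


def select_expression_extremes(
    intensities: pd.Series, params: AnalysisParams | None = None
) -> StrataAssignment:
    """Split into top-q / bottom-q / mid strata by log2 intensity.

    With n values and quantile fraction q, the k = ceil(q*n) lowest values
    (ties at the threshold included) are "low" and the k highest "high" --
    order-statistic (type-1) quantiles.  Requires n >= ceil(1/q).
    """
    params = params or AnalysisParams()
    q = params.exon_quantile
    values = intensities.dropna().astype(float)
    n = len(values)
    if n < math.ceil(1.0 / q - 1e-9):
        raise ValueError(f"too few values ({n}) for quantile {q}")
    k = math.ceil(q * n - 1e-9)
    ordered = np.sort(values.to_numpy())
    low_thr = float(ordered[k - 1])
    high_thr = float(ordered[n - k])
    strata = pd.Series("mid", index=intensities.index, dtype=object)
    strata[intensities.isna()] = np.nan
    if low_thr >= high_thr:
        return StrataAssignment(strata, True, low_thr, high_thr)
    strata[values.index[values <= low_thr]] = "low"
    strata[values.index[values >= high_thr]] = "high"
    return StrataAssignment(strata, False, low_thr, high_thr)


def _feature_row(
    gene: GeneModel,
    track: SignalTrack,
    params: AnalysisParams,
    role: str,
    ordinal: int,
    interval: tuple[int, int],
) -> dict:
    region = Region(gene.chrom, interval[0], interval[1], gene.strand,
                    "exon" if "exon" in role else "intron")
    values = assign_probe_values(track, region, params)
    mean = float(values.mean()) if len(values) >= params.min_probes else np.nan
    return {
        "gene_id": gene.gene_id,
        "mark": track.mark,
        "condition": track.condition,
        "role": role,
        "ordinal": ordinal,
        "start": interval[0],
        "end": interval[1],
        "mean_signal": mean,
        "n_probes": len(values),
    }


def exon_intron_summary(
    gene: GeneModel, track: SignalTrack, params: AnalysisParams | None = None
) -> pd.DataFrame:
    """Mean probe signal per exon and intron, transcriptional order.

    Exons are tagged first_exon / last_exon / internal (first and last only
    for genes with >= 2 exons); introns are the gaps between consecutive
    exons.  For single-exon genes the frame holds only the internal exon and
    ``attrs["single_exon"]`` is set.
    """
    params = params or AnalysisParams()
    exons_t = gene.transcriptional_order(gene.exons)
    introns_t = gene.transcriptional_order(gene.introns)
    rows = []
    single = len(exons_t) < 2
    for i, iv in enumerate(exons_t, start=1):
        if single:
            role = "internal"
        elif i == 1:
            role = "first_exon"
        elif i == len(exons_t):
            role = "last_exon"
        else:
            role = "internal"
        rows.append(_feature_row(gene, track, params, role, i, iv))
    if not single:
        for i, iv in enumerate(introns_t, start=1):
            rows.append(_feature_row(gene, track, params, "intron", i, iv))
    out = pd.DataFrame(rows)
    out.attrs["single_exon"] = single
    return out


def coding_exon_summary(
    gene: GeneModel, track: SignalTrack, params: AnalysisParams | None = None
) -> pd.DataFrame:
    """First/last coding exon mean signals (transcriptional order).

    Coding exons are the exons intersected with the CDS interval; genes
    without a CDS or with fewer than two coding exons produce an empty frame
    with ``attrs["skipped"]`` set.
    """
    params = params or AnalysisParams()
    coding = gene.transcriptional_order(gene.coding_exons())
    cols = ["gene_id", "mark", "condition", "role", "ordinal", "start", "end",
            "mean_signal", "n_probes"]
    if not gene.coding:
        out = pd.DataFrame(columns=cols)
        out.attrs["skipped"] = "non_coding"
        return out
    if len(coding) < 2:
        out = pd.DataFrame(columns=cols)
        out.attrs["skipped"] = "fewer_than_two_coding_exons"
        return out
    rows = [
        _feature_row(gene, track, params, "first_coding_exon", 1, coding[0]),
        _feature_row(gene, track, params, "last_coding_exon", len(coding), coding[-1]),
    ]
    return pd.DataFrame(rows)


def classify_differential(
    expr: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Per-gene up/down/unchanged status from log2 intensity change.

    delta = log2(b) - log2(a); "up" iff delta >= diff_log2, "down" iff
    delta <= -diff_log2 (inclusive thresholds).  Genes missing a value in
    either condition get a missing status.
    """
    params = params or AnalysisParams()
    for cond in (cond_a, cond_b):
        if cond not in expr.columns:
            raise KeyError(f"condition {cond!r} not in expression table")
    delta = expr[cond_b] - expr[cond_a]
    status = pd.Series(np.nan, index=expr.index, dtype=object)
    defined = delta.notna()
    status[defined & (delta >= params.diff_log2)] = "up"
    status[defined & (delta <= -params.diff_log2)] = "down"
    status[defined & status.isna()] = "unchanged"
    return pd.DataFrame({"delta": delta, "status": status})


@dataclass(frozen=True)
class ExpressionCpgResult:
    correlation: CorrelationResult
    scatter: pd.DataFrame


def expression_change_vs_cpg(
    delta: pd.Series,
    cpg: pd.Series,
    znf: pd.Series | None = None,
) -> ExpressionCpgResult:
    """Pearson R between expression change and gene-body CpG density.

    Returns the correlation plus a gene-labelled scatter table (ZNF genes
    flagged when a label vector is supplied) ready for export.
    """
    corr = pearson_correlation(delta, cpg)
    scatter = pd.DataFrame({"delta_log2": delta, "cpg_body_per_kb": cpg})
    scatter["znf"] = znf.reindex(scatter.index).fillna(False) if znf is not None else False
    scatter = scatter.dropna(subset=["delta_log2", "cpg_body_per_kb"])
    scatter.index.name = "gene_id"
    return ExpressionCpgResult(corr, scatter)


def boxplot_stats(values) -> dict:
    """Five-number summary {min, q1, median, q3, max, n} of finite values."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) == 0:
        return {"min": np.nan, "q1": np.nan, "median": np.nan,
                "q3": np.nan, "max": np.nan, "n": 0}
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {"min": float(arr.min()), "q1": float(q1), "median": float(med),
            "q3": float(q3), "max": float(arr.max()), "n": int(len(arr))}
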