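"""Gene x mark coverage tables, marked-gene classification and statistics.

The central object is the :class:`MarkCoverageTable`: for every gene and
every (mark, condition) track, the fraction of gene-body probes whose log2
ratio exceeds the positivity threshold, together with the mean signal and
probe count.  A gene is "marked" when its positive-probe coverage is at or
above ``theta_cov`` (default 20%); genes whose track has no probes in the
gene body are excluded from that mark's denominator rather than counted as
unmarked.

Classification vectors feed 2x2 co-occupancy counts, chi-square and Fisher
exact tests, Pearson correlations between per-gene signal summaries, and
pairwise Mann-Whitney group comparisons with Bonferroni correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnalysisParams, GeneModel, cpg_density, derive_regions
from .signal_io import SignalTrack, assign_probe_values

__all__ = [
    "MarkCoverageTable",
    "build_coverage_table",
    "classify_marked_genes",
    "CooccupancyResult",
    "cooccupancy_counts",
    "ChiSquareResult",
    "chi_square_test",
    "FisherResult",
    "fisher_exact_test",
    "CorrelationResult",
    "pearson_correlation",
    "group_signal_comparison",
]


@dataclass
class MarkCoverageTable:
    """Per-gene coverage fractions, mean signals and probe counts.

    The three frames share an index of gene ids and MultiIndex columns of
    (mark, condition).  ``meta`` carries per-gene annotations (symbol,
    strand, length, labels, optional gene-body CpG density).
    """

    coverage: pd.DataFrame
    mean_signal: pd.DataFrame
    n_probes: pd.DataFrame
    meta: pd.DataFrame
    region_role: str = "gene_body"

    def __post_init__(self) -> None:
        for frame in (self.mean_signal, self.n_probes, self.meta):
            if not frame.index.equals(self.coverage.index):
                raise ValueError("coverage table frames must share one gene index")
        cov = self.coverage.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if np.nanmin(cov, initial=0.0) < 0 or np.nanmax(cov, initial=0.0) > 1:
                raise ValueError("coverage fractions must lie in [0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.coverage.index

    def column(self, mark: str, condition: str | None = None) -> tuple[str, str]:
        """Resolve (mark, condition); condition may be omitted if unique."""
        if mark not in self.coverage.columns.get_level_values(0):
            raise KeyError(f"unknown mark {mark!r}")
        if condition is None:
            conds = self.coverage[mark].columns
            if len(conds) != 1:
                raise KeyError(
                    f"mark {mark!r} present in conditions {list(conds)}; specify one"
                )
            condition = conds[0]
        if (mark, condition) not in self.coverage.columns:
            raise KeyError(f"no track for mark {mark!r} in condition {condition!r}")
        return mark, condition

    def to_frame(self) -> pd.DataFrame:
        """Flat single frame with columns ``mark|condition|field``."""
        parts = {}
        for name, frame in (
            ("coverage", self.coverage),
            ("mean", self.mean_signal),
            ("n_probes", self.n_probes),
        ):
            f = frame.copy()
            f.columns = [f"{m}|{c}|{name}" for m, c in frame.columns]
            parts[name] = f
        out = pd.concat([self.meta] + list(parts.values()), axis=1)
        out.index.name = "gene_id"
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def build_coverage_table(
    genes: Sequence[GeneModel],
    tracks: Iterable[SignalTrack],
    params: AnalysisParams | None = None,
    genome: Mapping[str, object] | None = None,
    region_role: str = "gene_body",
) -> MarkCoverageTable:
    """Summarise every track over every gene's ``region_role`` region.

    ``genome`` maps chromosome name to a sliceable sequence (a dict of
    strings or a ``pyfaidx.Fasta``); when given, per-gene body CpG density
    is added to the metadata.
    """
    params = params or AnalysisParams()
    tracks = list(tracks)
    cols = pd.MultiIndex.from_tuples(
        [(t.mark, t.condition) for t in tracks], names=["mark", "condition"]
    )
    if cols.duplicated().any():
        raise ValueError("duplicate (mark, condition) track")
    index = pd.Index([g.gene_id for g in genes], name="gene_id")
    if index.duplicated().any():
        raise ValueError("duplicate gene_id in gene list")

    cov = np.full((len(genes), len(tracks)), np.nan)
    mean = np.full_like(cov, np.nan)
    nprobes = np.zeros(cov.shape, dtype=np.int64)
    meta_rows = []
    for i, gene in enumerate(genes):
        region = derive_regions(gene, params)[region_role]
        for j, track in enumerate(tracks):
            values = assign_probe_values(track, region, params)
            n = len(values)
            nprobes[i, j] = n
            if n > 0:
                cov[i, j] = np.count_nonzero(values > params.theta_pos) / n
            if n >= params.min_probes:
                mean[i, j] = values.mean()
        row = {
            "symbol": gene.symbol,
            "chrom": gene.chrom,
            "strand": gene.strand,
            "length": gene.length,
            "znf": "ZNF" in gene.labels,
        }
        if genome is not None:
            body = derive_regions(gene, params)["gene_body"]
            seq = str(genome[gene.chrom][body.start:body.end])
            row["cpg_body_per_kb"] = cpg_density(seq, body, params)
        meta_rows.append(row)

    return MarkCoverageTable(
        coverage=pd.DataFrame(cov, index=index, columns=cols),
        mean_signal=pd.DataFrame(mean, index=index, columns=cols),
        n_probes=pd.DataFrame(nprobes, index=index, columns=cols),
        meta=pd.DataFrame(meta_rows, index=index),
        region_role=region_role,
    )


def classify_marked_genes(
    table: MarkCoverageTable,
    mark: str,
    params: AnalysisParams | None = None,
    condition: str | None = None,
) -> pd.Series:
    """Boolean "marked" vector for one mark.

    Marked iff coverage >= ``theta_cov`` (inclusive).  Genes with missing
    coverage (no probes assigned) come back as ``pd.NA`` -- excluded from
    any downstream denominator.
    """
    params = params or AnalysisParams()
    key = table.column(mark, condition)
    cov = table.coverage[key]
    out = pd.Series(pd.NA, index=cov.index, dtype="boolean", name=mark)
    defined = cov.notna()
    out[defined] = cov[defined] >= params.theta_cov
    return out


@dataclass(frozen=True)
class CooccupancyResult:
    only_a: int
    only_b: int
    both: int
    neither: int
    n_universe: int
    table: pd.DataFrame  # rows: mark_a status, cols: mark_b status

    def as_dict(self) -> dict:
        return {
            "only_a": self.only_a,
            "only_b": self.only_b,
            "both": self.both,
            "neither": self.neither,
            "n_universe": self.n_universe,
        }


def cooccupancy_counts(marked_a: pd.Series, marked_b: pd.Series) -> CooccupancyResult:
    """Cross-classify two marked-gene vectors over their shared universe.

    Both vectors must cover the same gene universe; genes excluded (NA) in
    either vector are dropped from both before counting.
    """
    if not marked_a.index.equals(marked_b.index):
        raise ValueError("marked vectors are over different gene universes")
    keep = marked_a.notna() & marked_b.notna()
    a = marked_a[keep].astype(bool)
    b = marked_b[keep].astype(bool)
    both = int((a & b).sum())
    only_a = int((a & ~b).sum())
    only_b = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    name_a = marked_a.name or "mark_a"
    name_b = marked_b.name or "mark_b"
    table = pd.DataFrame(
        [[both, only_a], [only_b, neither]],
        index=pd.Index([f"{name_a}+", f"{name_a}-"]),
        columns=pd.Index([f"{name_b}+", f"{name_b}-"]),
    )
    return CooccupancyResult(only_a, only_b, both, neither, int(keep.sum()), table)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def _as_count_matrix(table) -> np.ndarray:
    arr = np.asarray(getattr(table, "values", table), dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table must hold non-negative integers")
    if arr.sum() < 1:
        raise ValueError("contingency table grand total must be >= 1")
    return arr


def chi_square_test(table) -> ChiSquareResult:
    """Pearson chi-square without continuity correction.

    df = (r-1)(c-1); p from the upper tail.  A zero row/column margin is an
    error (use :func:`fisher_exact_test` instead).
    """
    arr = _as_count_matrix(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError(
            "contingency table has a zero margin; use fisher_exact_test"
        )
    expected = stats.contingency.expected_freq(arr)
    if np.any(expected < 5):
        warnings.warn(
            "expected cell count < 5; Fisher's exact test is recommended"
        )
    statistic, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return ChiSquareResult(float(statistic), int(df), float(p))


@dataclass(frozen=True)
class FisherResult:
    p_two_tailed: float
    odds_ratio: float


def fisher_exact_test(table) -> FisherResult:
    """Two-tailed Fisher exact test on a 2x2 table.

    Two-tailed by the probability-mass rule: the p-value sums the
    hypergeometric probabilities of all tables with the same margins whose
    probability does not exceed the observed table's.
    """
    arr = _as_count_matrix(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return FisherResult(float(p), float(odds))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson R with a two-sided t-test on n-2 df.

    Series inputs are aligned on their index; pairs with a missing value in
    either vector are dropped.  Requires n >= 3 and non-constant vectors.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        x, y = x.align(y, join="inner")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    n = len(xa)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("undefined correlation: constant vector")
    r, p = stats.pearsonr(xa, ya)
    return CorrelationResult(float(r), float(p), n)


def group_signal_comparison(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All pairwise two-sided Mann-Whitney U tests, Bonferroni-corrected.

    Returns one row per unordered pair with the U statistic, raw p, and the
    p multiplied by the number of pairs (capped at 1).
    """
    cleaned: dict[str, np.ndarray] = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        cleaned[name] = arr
    if len(cleaned) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(itertools.combinations(sorted(cleaned), 2))
    rows = []
    for a, b in pairs:
        u, p = stats.mannwhitneyu(cleaned[a], cleaned[b], alternative="two-sided")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(cleaned[a]),
                "n_b": len(cleaned[b]),
                "u": float(u),
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * len(pairs))),
            }
        )
    return pd.DataFrame(rows)
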