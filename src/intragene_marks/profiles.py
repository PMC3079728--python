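"""Metagene binning, composite (group-average) profiles, clustered matrices.

Every gene is summarised as a strand-oriented vector of 40 bins by default:
10 bins over the 5 kb upstream flank, 20 near-equal bins over the gene body,
and 10 bins over the 5 kb downstream flank, with index 0 always the 5'-most
bin.  Per-bin values are unweighted means of the probes whose midpoints fall
in the bin; empty bins are missing (NaN), never zero.  Composite profiles
average each bin over the genes that have a defined value there.

Body bins: with gene length L and n bins, the first (L mod n) bins counted
from the 5' end get one extra base, so the bins always tile the body
exactly.  Flank bins use the same rule (the default 5000/10 divides evenly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .annotations import AnalysisParams, GeneModel
from .signal_io import SignalTrack

__all__ = [
    "BinProfile",
    "CompositeProfile",
    "ProfileMatrix",
    "oriented_bin_intervals",
    "assign_bin_indices",
    "bin_gene_profile",
    "composite_profile",
    "build_profile_matrix",
    "cluster_profile_matrix",
    "chromosome_mean_signal",
    "heatmap_matrix",
]


@dataclass(frozen=True)
class BinProfile:
    """One gene x one track: oriented per-bin means and probe counts."""

    gene_id: str
    mark: str
    condition: str
    values: np.ndarray  # float, NaN where no probes
    n_probes: np.ndarray  # int

    def __post_init__(self) -> None:
        if self.values.shape != self.n_probes.shape:
            raise ValueError("values and n_probes must have the same shape")
        if np.any(np.isnan(self.values) != (self.n_probes == 0)):
            raise ValueError("bins are missing exactly when they hold no probes")


@dataclass(frozen=True)
class CompositeProfile:
    """Per-bin mean over a gene group, with contributing-gene counts and SEM."""

    label: str
    mark: str
    condition: str
    mean: np.ndarray
    n_genes: np.ndarray
    sem: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": np.arange(len(self.mean)), "mean": self.mean,
             "n_genes": self.n_genes, "sem": self.sem}
        )


@dataclass(frozen=True)
class ProfileMatrix:
    """Gene x bin matrix reordered by hierarchical clustering."""

    data: pd.DataFrame  # original (non-imputed) values, rows in leaf order
    leaf_order: tuple[str, ...]
    linkage: np.ndarray


def _sizes(length: int, n: int) -> np.ndarray:
    """Bin sizes 5'->3': the first (length mod n) bins get one extra base."""
    base, rem = divmod(length, n)
    return np.array([base + 1] * rem + [base] * (n - rem), dtype=np.int64)


def oriented_bin_intervals(
    gene: GeneModel, params: AnalysisParams | None = None
) -> np.ndarray:
    """Genomic (start, end) of every oriented bin, index 0 = 5'-most.

    Shape (total_bins, 2).  Flank bins may have negative genomic coordinates
    when a gene sits near the chromosome start; probes cannot fall there, so
    such bins are simply empty.
    """
    params = params or AnalysisParams()
    nb, nf, fl = params.n_body_bins, params.n_flank_bins, params.flank_bp
    L = gene.length
    if L < nb:
        raise ValueError(
            f"{gene.gene_id}: gene length {L} shorter than {nb} body bins"
        )
    body_sizes = _sizes(L, nb)
    flank_sizes = _sizes(fl, nf)
    out = np.empty((nb + 2 * nf, 2), dtype=np.int64)
    if gene.strand == "+":
        # upstream flank: 5'-most bin is the leftmost (farthest upstream)
        edges = gene.tx_start - fl + np.concatenate(([0], np.cumsum(flank_sizes)))
        out[:nf, 0], out[:nf, 1] = edges[:-1], edges[1:]
        edges = gene.tx_start + np.concatenate(([0], np.cumsum(body_sizes)))
        out[nf:nf + nb, 0], out[nf:nf + nb, 1] = edges[:-1], edges[1:]
        edges = gene.tx_end + np.concatenate(([0], np.cumsum(flank_sizes)))
        out[nf + nb:, 0], out[nf + nb:, 1] = edges[:-1], edges[1:]
    else:
        # minus strand: 5' is the right end; oriented bins run right-to-left
        edges = gene.tx_end + fl - np.concatenate(([0], np.cumsum(flank_sizes)))
        out[:nf, 0], out[:nf, 1] = edges[1:], edges[:-1]
        edges = gene.tx_end - np.concatenate(([0], np.cumsum(body_sizes)))
        out[nf:nf + nb, 0], out[nf:nf + nb, 1] = edges[1:], edges[:-1]
        edges = gene.tx_start - np.concatenate(([0], np.cumsum(flank_sizes)))
        out[nf + nb:, 0], out[nf + nb:, 1] = edges[1:], edges[:-1]
    return out


def assign_bin_indices(
    gene: GeneModel,
    midpoints: np.ndarray,
    params: AnalysisParams | None = None,
) -> np.ndarray:
    """Oriented bin index for each probe midpoint (-1 when outside all bins)."""
    params = params or AnalysisParams()
    intervals = oriented_bin_intervals(gene, params)
    order = np.argsort(intervals[:, 0], kind="stable")
    lefts = intervals[order, 0]
    rights = intervals[order, 1]
    mids = np.asarray(midpoints, dtype=np.int64)
    pos = np.searchsorted(lefts, mids, side="right") - 1
    pos_clip = np.clip(pos, 0, len(lefts) - 1)
    inside = (pos >= 0) & (mids < rights[pos_clip])
    result = np.full(len(mids), -1, dtype=np.int64)
    result[inside] = order[pos_clip[inside]]
    return result


def bin_gene_profile(
    gene: GeneModel, track: SignalTrack, params: AnalysisParams | None = None
) -> BinProfile:
    """Oriented per-bin mean probe signal for one gene and one track."""
    params = params or AnalysisParams()
    intervals = oriented_bin_intervals(gene, params)
    lo = max(0, int(intervals[:, 0].min()))
    hi = int(intervals[:, 1].max())
    d = track.arrays(gene.chrom)
    mids = d["mids"]
    i0 = np.searchsorted(mids, lo, side="left")
    i1 = np.searchsorted(mids, hi, side="left")
    idx = assign_bin_indices(gene, mids[i0:i1], params)
    values = d["values"][i0:i1]
    total = params.total_bins
    keep = idx >= 0
    counts = np.bincount(idx[keep], minlength=total)
    sums = np.bincount(idx[keep], weights=values[keep], minlength=total)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinProfile(gene.gene_id, track.mark, track.condition, means, counts)


def composite_profile(
    profiles: Sequence[BinProfile], label: str = "group"
) -> CompositeProfile:
    """Bin-wise mean over genes; missing bins drop out of both numerator and
    denominator.  SEM uses the per-bin ddof-1 standard deviation."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty gene group")
    mark = profiles[0].mark
    condition = profiles[0].condition
    nbins = len(profiles[0].values)
    for p in profiles:
        if p.mark != mark or p.condition != condition or len(p.values) != nbins:
            raise ValueError("profiles must share mark, condition and bin count")
    stack = np.vstack([p.values for p in profiles])
    n = np.sum(np.isfinite(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return CompositeProfile(label, mark, condition, mean, n, sem)


def build_profile_matrix(
    genes: Sequence[GeneModel],
    tracks: Iterable[SignalTrack],
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Genes x (mark, bin) matrix of oriented bin means across tracks."""
    params = params or AnalysisParams()
    tracks = list(tracks)
    blocks = []
    index = pd.Index([g.gene_id for g in genes], name="gene_id")
    for track in tracks:
        rows = np.vstack(
            [bin_gene_profile(g, track, params).values for g in genes]
        )
        cols = pd.MultiIndex.from_product(
            [[track.mark], range(params.total_bins)], names=["mark", "bin"]
        )
        blocks.append(pd.DataFrame(rows, index=index, columns=cols))
    return pd.concat(blocks, axis=1)


def cluster_profile_matrix(
    matrix: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
) -> ProfileMatrix:
    """Order genes by agglomerative clustering of their bin vectors.

    Rows are first sorted by gene id (the documented deterministic
    tie-break), missing bins are imputed as the column mean for the distance
    computation only, and all-missing rows are dropped with a warning.  The
    returned matrix holds the original (non-imputed) values in dendrogram
    leaf order.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 genes to cluster")
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} gene(s) with all-missing profiles"
        )
        matrix = matrix.loc[~all_missing]
    matrix = matrix.sort_index(kind="stable")
    filled = matrix.to_numpy(dtype=float).copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(filled, axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    nan_mask = ~np.isfinite(filled)
    filled[nan_mask] = np.broadcast_to(col_means, filled.shape)[nan_mask]
    link = hierarchy.linkage(pdist(filled, metric=metric), method=method)
    order = hierarchy.leaves_list(link)
    data = matrix.iloc[order]
    return ProfileMatrix(data, tuple(data.index), link)


def chromosome_mean_signal(track: SignalTrack, chrom: str | None = None) -> float:
    """Mean probe signal over one chromosome (or the whole track)."""
    chroms = [chrom] if chrom else track.chroms
    values = np.concatenate([track.arrays(c)["values"] for c in chroms])
    if len(values) == 0:
        raise ValueError("track has no probes")
    return float(values.mean())


def heatmap_matrix(
    matrix: pd.DataFrame,
    center: Mapping[str, float],
    clip: float = 2.0,
) -> pd.DataFrame:
    """Display-only transform: center each mark at its chromosome-wide mean
    signal and saturate symmetrically at +/-clip log2 units.  Never feeds
    statistics."""
    out = matrix.copy()
    for mark in out.columns.get_level_values(0).unique():
        out[mark] = (out[mark] - center[mark]).clip(-clip, clip)
    return out


def plot_composites(composites: Sequence[CompositeProfile], path, title: str = "") -> None:
    """Optional rendering of composite profiles (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for comp in composites:
        ax.plot(np.arange(len(comp.mean)), comp.mean, label=f"{comp.mark} ({comp.label})")
    ax.set_xlabel("bin (5' flank | gene body | 3' flank)")
    ax.set_ylabel("mean log2 ratio")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
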