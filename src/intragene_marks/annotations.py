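"""Gene models, analysis regions, CpG density and gene-class labels.

This module defines the coordinate layer of the pipeline.  Every analysis
downstream (probe-level signal summaries, gene-body coverage classification,
metagene binning, exon-level summaries) operates on regions derived from a
transcript model:

* the *gene body* runs from the transcription start site (TSS) to the end of
  the transcript, in the transcribed orientation;
* the *promoter* is a fixed window around the TSS (default +/-500 bp);
* 5 kb *flanks* extend upstream of the TSS and downstream of the transcript
  end, used for metagene profiles.

All coordinates are 0-based, half-open (BED convention) internally; refFlat
input, which is already half-open in the UCSC dump format, maps directly.
CpG density is a plain dinucleotide count scaled to counts per kilobase and
is strand-independent because CpG is self-complementary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneModel",
    "Region",
    "AnalysisParams",
    "AnnotationParseError",
    "read_gene_models",
    "derive_regions",
    "cpg_density",
    "label_gene_class",
    "write_regions_bed6",
]

REGION_ROLES = (
    "promoter",
    "gene_body",
    "upstream_flank",
    "downstream_flank",
    "exon",
    "intron",
)


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed; names the line."""


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable thresholds and geometry of the analysis.

    Attributes
    ----------
    theta_pos:
        log2-ratio above which a probe is called positive (strictly greater
        than; a probe exactly at the threshold is *not* positive).
    theta_cov:
        Fraction of positive probes in the gene body at or above which a gene
        is called marked (inclusive).
    n_body_bins, n_flank_bins, flank_bp:
        Metagene geometry: the gene body is split into ``n_body_bins``
        near-equal bins and each ``flank_bp`` flank into ``n_flank_bins``.
    promoter_up, promoter_down:
        Promoter extent upstream/downstream of the TSS in transcriptional
        orientation.  The default is the symmetric +/-500 bp window; a
        -1000/+500 variant is obtained by setting ``promoter_up=1000``.
    cpg_scale:
        Length unit for CpG density (1000 => counts per kb).
    exon_quantile:
        Fraction of exons taken at each expression extreme (0.15 => top and
        bottom 15%).
    diff_log2:
        Absolute log2 expression change at or above which a gene is called
        up/down regulated (inclusive).
    min_probes:
        Minimum assigned probes for a region mean to be defined.
    min_probes_corr:
        Minimum assigned probes for a gene to enter correlation analyses.
    membership:
        Probe-to-region membership rule: ``"midpoint"`` (default) or
        ``"overlap"`` (any overlap).
    """

    theta_pos: float = 1.0
    theta_cov: float = 0.20
    n_body_bins: int = 20
    n_flank_bins: int = 10
    flank_bp: int = 5000
    promoter_up: int = 500
    promoter_down: int = 500
    cpg_scale: int = 1000
    exon_quantile: float = 0.15
    diff_log2: float = 0.5
    min_probes: int = 1
    min_probes_corr: int = 5
    membership: str = "midpoint"

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta_pos):
            raise ValueError("theta_pos must be finite")
        if not 0.0 < self.theta_cov <= 1.0:
            raise ValueError("theta_cov must be in (0, 1]")
        if not 0.0 < self.exon_quantile < 0.5:
            raise ValueError("exon_quantile must be in (0, 0.5)")
        if self.n_body_bins < 1 or self.n_flank_bins < 1:
            raise ValueError("bin counts must be >= 1")
        if min(self.flank_bp, self.promoter_up, self.promoter_down) < 0:
            raise ValueError("extents must be non-negative")
        if self.cpg_scale <= 0:
            raise ValueError("cpg_scale must be positive")
        if self.diff_log2 < 0 or not math.isfinite(self.diff_log2):
            raise ValueError("diff_log2 must be finite and non-negative")
        if self.min_probes < 1 or self.min_probes_corr < 1:
            raise ValueError("min_probes thresholds must be >= 1")
        if self.membership not in ("midpoint", "overlap"):
            raise ValueError("membership must be 'midpoint' or 'overlap'")

    @property
    def total_bins(self) -> int:
        return self.n_body_bins + 2 * self.n_flank_bins


@dataclass(frozen=True)
class GeneModel:
    """One transcript: span, strand, exon/CDS structure and class labels."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None
    labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        prev_end = None
        for s, e in self.exons:
            if not s < e:
                raise ValueError(f"{self.gene_id}: empty exon ({s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(
                    f"{self.gene_id}: exon ({s},{e}) outside transcript span"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.gene_id}: cds_start/cds_end must both be set")
        if self.cds_start is not None:
            if not self.tx_start <= self.cds_start < self.cds_end <= self.tx_end:
                raise ValueError(f"{self.gene_id}: CDS outside transcript span")
        object.__setattr__(self, "labels", frozenset(self.labels))

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def tss(self) -> int:
        """Transcription start site (tx_end for minus-strand genes)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        """Transcript end in transcriptional orientation."""
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order."""
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return tuple(out)

    @property
    def coding(self) -> bool:
        return self.cds_start is not None

    def coding_exons(self) -> tuple[tuple[int, int], ...]:
        """Exons intersected with the CDS interval (genomic order)."""
        if not self.coding:
            return ()
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return tuple(out)

    def transcriptional_order(
        self, intervals: Sequence[tuple[int, int]]
    ) -> tuple[tuple[int, int], ...]:
        """Order intervals 5'->3' (reversed genomic order on minus strand)."""
        ivs = tuple(intervals)
        return ivs if self.strand == "+" else ivs[::-1]


@dataclass(frozen=True)
class Region:
    """A genomic interval with a role in the analysis.

    Regions produced by clipping at the chromosome start may be empty
    (start == end); such regions simply contain no probes.
    """

    chrom: str
    start: int
    end: int
    strand: str
    role: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.role not in REGION_ROLES:
            raise ValueError(f"unknown region role {self.role!r}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def empty(self) -> bool:
        return self.start == self.end


def _clip_interval(start: int, end: int, role: str, gene_id: str) -> tuple[int, int]:
    if start < 0:
        start = 0
    if end < start:
        end = start
    if start == end:
        warnings.warn(
            f"{gene_id}: {role} is empty after clipping at the chromosome start"
        )
    return start, end


def derive_regions(gene: GeneModel, params: AnalysisParams | None = None) -> dict[str, Region]:
    """Return the gene's analysis regions keyed by role.

    The gene body is the transcript span.  The promoter spans
    ``promoter_up`` bp 5' and ``promoter_down`` bp 3' of the TSS in
    transcriptional orientation.  Flanks of ``flank_bp`` sit 5' of the TSS
    and 3' of the transcript end.  Intervals are clipped at position 0;
    fully clipped intervals come back empty (with a warning), never missing.
    """
    params = params or AnalysisParams()
    if gene.strand == "+":
        promoter = (gene.tx_start - params.promoter_up, gene.tx_start + params.promoter_down)
        upstream = (gene.tx_start - params.flank_bp, gene.tx_start)
        downstream = (gene.tx_end, gene.tx_end + params.flank_bp)
    else:
        promoter = (gene.tx_end - params.promoter_down, gene.tx_end + params.promoter_up)
        upstream = (gene.tx_end, gene.tx_end + params.flank_bp)
        downstream = (gene.tx_start - params.flank_bp, gene.tx_start)

    def mk(role: str, iv: tuple[int, int]) -> Region:
        s, e = _clip_interval(iv[0], iv[1], role, gene.gene_id)
        return Region(gene.chrom, s, e, gene.strand, role)

    return {
        "gene_body": Region(gene.chrom, gene.tx_start, gene.tx_end, gene.strand, "gene_body"),
        "promoter": mk("promoter", promoter),
        "upstream_flank": mk("upstream_flank", upstream),
        "downstream_flank": mk("downstream_flank", downstream),
    }


def cpg_density(
    sequence: str,
    region: Region | None = None,
    params: AnalysisParams | None = None,
) -> float:
    """CpG dinucleotides per ``cpg_scale`` bp of ``sequence``.

    ``sequence`` must cover the region exactly when a region is given.  The
    count is of non-overlapping-by-nature "CG" dinucleotides and is the same
    on either strand.
    """
    params = params or AnalysisParams()
    n = len(sequence)
    if n == 0:
        raise ValueError("cannot compute CpG density of an empty sequence")
    if region is not None and n != region.length:
        raise ValueError(
            f"sequence length {n} does not match region length {region.length}"
        )
    count = sequence.upper().count("CG")
    return count / n * params.cpg_scale


def write_regions_bed6(
    genes: Iterable[GeneModel],
    path: str | Path,
    params: AnalysisParams | None = None,
) -> None:
    """Export every gene's analysis regions as BED6, role in the name field."""
    params = params or AnalysisParams()
    with open(path, "wt") as fh:
        for gene in genes:
            for role, region in derive_regions(gene, params).items():
                if region.empty:
                    continue
                fh.write(
                    f"{region.chrom}\t{region.start}\t{region.end}\t"
                    f"{gene.gene_id}|{role}\t0\t{region.strand}\n"
                )


def label_gene_class(
    genes: Iterable[GeneModel],
    znf_prefix: str = "ZNF",
    override_list: Iterable[str] | None = None,
) -> list[GeneModel]:
    """Attach the "ZNF" label to zinc-finger genes.

    A gene is labelled iff its symbol starts with ``znf_prefix``
    (case-sensitive) or its symbol appears in ``override_list``.  Returns new
    GeneModel instances; unlabelled genes are passed through unchanged.
    """
    override = frozenset(override_list or ())
    out = []
    for g in genes:
        if not g.symbol:
            raise ValueError(f"{g.gene_id}: empty gene symbol")
        if g.symbol.startswith(znf_prefix) or g.symbol in override:
            out.append(replace(g, labels=g.labels | {"ZNF"}))
        else:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# Annotation readers (BED12 and refFlat)
# ---------------------------------------------------------------------------

def _split_int_list(text: str, what: str, lineno: int) -> list[int]:
    try:
        return [int(x) for x in text.rstrip(",").split(",") if x != ""]
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: bad {what} list {text!r}") from exc


def _parse_bed12(fields: list[str], lineno: int) -> GeneModel:
    if len(fields) < 12:
        raise AnnotationParseError(
            f"line {lineno}: expected 12 BED fields, got {len(fields)}"
        )
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        name = fields[3]
        strand = fields[5]
        thick_start, thick_end = int(fields[6]), int(fields[7])
        block_count = int(fields[9])
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: non-numeric BED field") from exc
    sizes = _split_int_list(fields[10], "blockSizes", lineno)
    offsets = _split_int_list(fields[11], "blockStarts", lineno)
    if len(sizes) != block_count or len(offsets) != block_count:
        raise AnnotationParseError(
            f"line {lineno}: blockCount {block_count} does not match block lists"
        )
    exons = tuple(sorted((start + o, start + o + s) for o, s in zip(offsets, sizes)))
    cds_start = cds_end = None
    if thick_start != thick_end:
        cds_start, cds_end = thick_start, thick_end
    try:
        return GeneModel(
            gene_id=name, symbol=name, chrom=chrom, strand=strand,
            tx_start=start, tx_end=end, exons=exons,
            cds_start=cds_start, cds_end=cds_end,
        )
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: {exc}") from exc


def _parse_refflat(fields: list[str], lineno: int) -> GeneModel:
    if len(fields) < 11:
        raise AnnotationParseError(
            f"line {lineno}: expected 11 refFlat fields, got {len(fields)}"
        )
    symbol, name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
    try:
        tx_start, tx_end = int(fields[4]), int(fields[5])
        cds_start, cds_end = int(fields[6]), int(fields[7])
        exon_count = int(fields[8])
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: non-numeric refFlat field") from exc
    starts = _split_int_list(fields[9], "exonStarts", lineno)
    ends = _split_int_list(fields[10], "exonEnds", lineno)
    if len(starts) != exon_count or len(ends) != exon_count:
        raise AnnotationParseError(
            f"line {lineno}: exonCount {exon_count} does not match exon lists"
        )
    exons = tuple(sorted(zip(starts, ends)))
    # UCSC convention: cdsStart == cdsEnd marks a non-coding transcript.
    cds: tuple[int | None, int | None]
    cds = (None, None) if cds_start == cds_end else (cds_start, cds_end)
    try:
        return GeneModel(
            gene_id=name, symbol=symbol, chrom=chrom, strand=strand,
            tx_start=tx_start, tx_end=tx_end, exons=exons,
            cds_start=cds[0], cds_end=cds[1],
        )
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: {exc}") from exc


_PARSERS = {"bed12": _parse_bed12, "refflat": _parse_refflat}


def read_gene_models(path: str | Path, format: str = "refflat") -> list[GeneModel]:
    """Read transcript models from a BED12 or refFlat file.

    Coordinates are normalised to 0-based half-open and exon lists sorted by
    start.  Malformed lines raise :class:`AnnotationParseError` naming the
    line number; comment lines (``#``) and ``track``/``browser`` lines are
    skipped.
    """
    if format not in _PARSERS:
        raise ValueError(f"unknown annotation format {format!r}")
    parse = _PARSERS[format]
    genes: list[GeneModel] = []
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            genes.append(parse(line.split("\t"), lineno))
    return genes
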