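"""Self-contained synthetic chromosome with planted epigenetic gene classes.

The generator emulates a gene-dense chromosome tiled by a NimbleGen-style
probe grid, with four planted gene classes chosen to mirror the co-occupancy
structure seen on human chromosome 19:

* ``METH_ACTIVE`` -- high-CpG gene bodies carrying DNA methylation (MIRA)
  and H3K36me3, CpG-island promoters that are unmethylated (high UMC, low
  MIRA) and H3-acetylated;
* ``ZNF_LIKE`` -- low-CpG, zinc-finger-like gene bodies dually occupied by
  H3K9me3 and H3K36me3, with methylated promoters that demethylate and
  reactivate in the DNMT-knockout condition;
* ``POLYCOMB`` -- H3K27me3-covered, partially methylated repressed genes;
* ``INERT`` -- unmarked genes.

Probe values are a piecewise-constant class/condition target amplitude over
region roles (promoter, 5' and 3' body halves, flanks) plus homoscedastic
Gaussian noise on the log2 scale.  The UMC track is constructed
anticorrelated with MIRA at promoters.  H3K36me3 body amplitude is coupled
to the gene's expression level (elongation-mark behaviour), which is what
plants the high-vs-low expression stratum contrast at exon level.

Everything is driven by one integer seed: identical config + seed gives a
byte-identical fixture bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import GeneModel
from .signal_io import SignalTrack

__all__ = [
    "MARKS",
    "MarkProfile",
    "KnockoutEffect",
    "GeneClassSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "default_gene_classes",
    "flagship_config",
    "simulate_annotation",
    "simulate_sequence",
    "simulate_tracks",
    "simulate_expression",
    "simulate_dataset",
    "write_fixture_bundle",
    "validate_bundle",
    "write_bed12",
    "write_refflat",
]

MARKS = ("MIRA", "UMC", "H3K36me3", "H3K9me3", "H3K27me3", "H3ac", "H4K20me3")
_ROLES = ("promoter", "body5", "body3", "flank_up", "flank_down")

# rng stage tags so draws are independent of call order
_STAGE_ANNOT, _STAGE_SEQ, _STAGE_TRACKS, _STAGE_EXPR = 1, 2, 3, 4


@dataclass(frozen=True)
class MarkProfile:
    """Target log2 amplitudes of one mark over a gene's region roles."""

    promoter: float = 0.0
    body5: float = 0.0
    body3: float = 0.0
    flank_up: float = 0.0
    flank_down: float = 0.0

    def amplitudes(self) -> dict[str, float]:
        return {r: getattr(self, r) for r in _ROLES}


@dataclass(frozen=True)
class KnockoutEffect:
    """Condition-specific deltas applied on top of a class's targets.

    ``scale`` multiplies and ``set_to`` replaces the amplitude of
    (mark, role) pairs; the pseudo-role ``"body"`` expands to both body
    halves.  ``expression_delta`` shifts the gene's log2 intensity.
    """

    scale: tuple[tuple[str, str, float], ...] = ()
    set_to: tuple[tuple[str, str, float], ...] = ()
    expression_delta: float = 0.0

    def apply(self, mark: str, amps: dict[str, float]) -> dict[str, float]:
        def expand(role: str) -> tuple[str, ...]:
            return ("body5", "body3") if role == "body" else (role,)

        out = dict(amps)
        for m, role, value in self.set_to:
            if m == mark:
                for r in expand(role):
                    out[r] = value
        for m, role, factor in self.scale:
            if m == mark:
                for r in expand(role):
                    out[r] *= factor
        return out


@dataclass(frozen=True)
class GeneClassSpec:
    name: str
    proportion: float
    body_cpg_per_kb: tuple[float, float]  # mean, sd
    promoter_cpg_island: bool
    marks: Mapping[str, MarkProfile]
    expression_log2: tuple[float, float]  # mean, sd
    symbol_prefix: str = "GENE"
    knockout: Mapping[str, KnockoutEffect] = field(default_factory=dict)

    def mark_profile(self, mark: str) -> MarkProfile:
        return self.marks.get(mark, MarkProfile())

    def planted_body_marks(self, theta_pos: float = 1.0) -> frozenset[str]:
        """Marks whose body amplitude exceeds the positivity threshold."""
        out = set()
        for mark, prof in self.marks.items():
            if prof.body5 > theta_pos or prof.body3 > theta_pos:
                out.add(mark)
        return frozenset(out)


def _umc_promoter_from_mira(mira_promoter: float, high: float = 2.0, low: float = -1.0) -> float:
    """UMC is constructed anticorrelated with MIRA at promoters."""
    return high if mira_promoter <= 0.0 else low


def default_gene_classes(
    amplitude: float = 2.0,
    depleted: float = -1.0,
) -> tuple[GeneClassSpec, ...]:
    """The flagship class mix: 55/20/15/10% METH_ACTIVE/ZNF_LIKE/POLYCOMB/INERT."""

    def umc(mira: MarkProfile, body: float = 0.0) -> MarkProfile:
        return MarkProfile(
            promoter=_umc_promoter_from_mira(mira.promoter, amplitude, depleted),
            body5=body, body3=body,
        )

    meth_mira = MarkProfile(promoter=depleted, body5=amplitude, body3=amplitude)
    znf_mira = MarkProfile(promoter=amplitude)
    poly_mira = MarkProfile(promoter=depleted, body5=0.3, body3=0.3)
    inert_mira = MarkProfile()
    return (
        GeneClassSpec(
            name="METH_ACTIVE",
            proportion=0.55,
            body_cpg_per_kb=(25.0, 5.0),
            promoter_cpg_island=True,
            expression_log2=(8.0, 1.0),
            marks={
                "MIRA": meth_mira,
                "UMC": umc(meth_mira, body=depleted),
                "H3K36me3": MarkProfile(body5=amplitude, body3=amplitude),
                "H3ac": MarkProfile(promoter=amplitude),
            },
            knockout={
                "DKO": KnockoutEffect(
                    scale=(("MIRA", "body", 0.4),),
                    set_to=(("MIRA", "promoter", 0.0),),
                )
            },
        ),
        GeneClassSpec(
            name="ZNF_LIKE",
            proportion=0.20,
            body_cpg_per_kb=(6.0, 2.0),
            promoter_cpg_island=False,
            expression_log2=(5.0, 0.8),
            symbol_prefix="ZNF",
            marks={
                "MIRA": znf_mira,
                "UMC": umc(znf_mira),
                "H3K9me3": MarkProfile(body5=amplitude, body3=amplitude),
                "H3K36me3": MarkProfile(body5=amplitude, body3=amplitude),
            },
            knockout={
                "DKO": KnockoutEffect(
                    set_to=(("MIRA", "promoter", 0.0),),
                    scale=(("H3K9me3", "body", 0.3),),
                    expression_delta=0.8,
                )
            },
        ),
        GeneClassSpec(
            name="POLYCOMB",
            proportion=0.15,
            body_cpg_per_kb=(20.0, 5.0),
            promoter_cpg_island=True,
            expression_log2=(4.0, 0.8),
            marks={
                "MIRA": poly_mira,
                "UMC": umc(poly_mira, body=amplitude),
                "H3K27me3": MarkProfile(
                    promoter=amplitude, body5=amplitude, body3=amplitude
                ),
            },
            knockout={"DKO": KnockoutEffect(scale=(("MIRA", "body", 0.4),))},
        ),
        GeneClassSpec(
            name="INERT",
            proportion=0.10,
            body_cpg_per_kb=(10.0, 3.0),
            promoter_cpg_island=False,
            expression_log2=(5.5, 1.0),
            marks={"UMC": umc(inert_mira)},
        ),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 1000
    gene_length: tuple[int, int] = (6000, 16000)
    intergenic_gap: tuple[int, int] = (2000, 8000)
    exon_count: tuple[int, int] = (2, 12)
    probe_spacing: int = 100
    probe_length: int = 50
    noise_sd: float = 0.5
    expression_noise_sd: float = 0.1
    exon_expression_sd: float = 0.3
    k36_expression_coupling: float = 0.3
    intergenic_cpg_per_kb: float = 8.0
    island_cpg_per_kb: float = 80.0
    promoter_up: int = 500
    promoter_down: int = 500
    flank_bp: int = 5000
    flank_margin: int = 6000
    length_multiple: int = 20  # gene lengths rounded to n_body_bins
    noncoding_fraction: float = 0.1
    chrom: str = "chrS"
    conditions: tuple[str, ...] = ("WT", "DKO")
    marks: tuple[str, ...] = MARKS
    classes: tuple[GeneClassSpec, ...] = field(default_factory=default_gene_classes)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.probe_spacing <= 0 or self.probe_length <= 0:
            raise ValueError("probe spacing/length must be positive")
        if self.gene_length[0] < max(self.length_multiple, 2 * self.promoter_down):
            raise ValueError("gene_length lower bound infeasible")
        if self.gene_length[0] > self.gene_length[1]:
            raise ValueError("gene_length bounds inverted")
        total = sum(c.proportion for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if max(self.island_cpg_per_kb, *(c.body_cpg_per_kb[0] for c in self.classes)) > 500:
            raise ValueError("CpG density target > 500/kb is infeasible")

    @property
    def class_by_name(self) -> dict[str, GeneClassSpec]:
        return {c.name: c for c in self.classes}


def flagship_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default study conditions: 1000 genes, amplitude 2.0, noise 0.5."""
    return SyntheticConfig(seed=seed, **overrides)


def _rng(config: SyntheticConfig, stage: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stage, *extra])


def _class_counts(config: SyntheticConfig) -> np.ndarray:
    """Exact largest-remainder allocation of genes to classes."""
    props = np.array([c.proportion for c in config.classes])
    raw = props * config.n_genes
    counts = np.floor(raw).astype(int)
    frac_order = np.argsort(-(raw - counts), kind="stable")
    for k in range(config.n_genes - counts.sum()):
        counts[frac_order[k % len(counts)]] += 1
    return counts


def chromosome_length(genes: Sequence[GeneModel], config: SyntheticConfig) -> int:
    return max(g.tx_end for g in genes) + config.flank_margin


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    config: SyntheticConfig,
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place genes left-to-right with random gaps, strands and exon structure.

    Gene lengths are rounded down to a multiple of ``length_multiple`` so the
    default metagene body bins have identical sizes in either orientation.
    Class assignment uses exact largest-remainder counts with a seeded
    shuffle, so planted proportions hold exactly.  Returns the gene models
    plus a per-gene metadata frame (class, base expression, CpG target).
    """
    rng = _rng(config, _STAGE_ANNOT)
    counts = _class_counts(config)
    assignment = np.repeat(np.arange(len(config.classes)), counts)
    rng.shuffle(assignment)

    lmin, lmax = config.gene_length
    gmin, gmax = config.intergenic_gap
    emin, emax = config.exon_count
    min_seg = 30  # smallest exon/intron
    genes: list[GeneModel] = []
    meta_rows = []
    pos = config.flank_margin
    for i in range(config.n_genes):
        cls = config.classes[assignment[i]]
        pos += int(rng.integers(gmin, gmax + 1))
        L = int(rng.integers(lmin, lmax + 1))
        L -= L % config.length_multiple
        tx_start, tx_end = pos, pos + L
        pos = tx_end
        strand = "+" if rng.integers(2) == 0 else "-"
        n_ex = int(rng.integers(emin, emax + 1))
        nseg = 2 * n_ex - 1
        if L < min_seg * nseg:
            raise ValueError("gene too short for requested exon count")
        weights = rng.dirichlet(np.ones(nseg))
        seg = min_seg + rng.multinomial(L - min_seg * nseg, weights)
        bounds = tx_start + np.concatenate(([0], np.cumsum(seg)))
        exons = tuple(
            (int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_ex)
        )
        cds_start = cds_end = None
        if rng.random() >= config.noncoding_fraction:
            first_idx = 1 if (n_ex >= 3 and rng.random() < 0.3) else 0
            fs, fe = exons[first_idx]
            ls, le = exons[-1]
            cds_start = int(rng.integers(fs, fe - 2))
            cds_end = int(rng.integers(ls + 3, le + 1))
        gene_id = f"G{i:04d}"
        symbol = f"{cls.symbol_prefix}{i:04d}"
        genes.append(
            GeneModel(
                gene_id=gene_id, symbol=symbol, chrom=config.chrom,
                strand=strand, tx_start=tx_start, tx_end=tx_end, exons=exons,
                cds_start=cds_start, cds_end=cds_end,
            )
        )
        cm, cs = cls.body_cpg_per_kb
        target = float(np.clip(rng.normal(cm, cs), max(0.0, cm - 2 * cs), cm + 2 * cs))
        em, es = cls.expression_log2
        meta_rows.append(
            {
                "gene_id": gene_id,
                "symbol": symbol,
                "class_name": cls.name,
                "strand": strand,
                "tx_start": tx_start,
                "tx_end": tx_end,
                "length": L,
                "n_exons": n_ex,
                "base_expression": float(rng.normal(em, es)),
                "target_cpg_per_kb": target,
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("gene_id")
    return genes, meta


# ---------------------------------------------------------------------------
# Sequence
# ---------------------------------------------------------------------------

def simulate_sequence(
    genes: Sequence[GeneModel], meta: pd.DataFrame, config: SyntheticConfig
) -> str:
    """Realise one chromosome whose CpG content follows the planted targets.

    The background is random ACGT with every accidental CG dinucleotide
    broken; exact numbers of CpG dinucleotides are then placed per region
    (CpG-island promoters first, then gene bodies up to their per-gene
    budget, then intergenic stretches), so the realised per-gene body
    density stays within a few percent of its drawn target.
    """
    rng = _rng(config, _STAGE_SEQ)
    clen = chromosome_length(genes, config)
    bg = rng.integers(0, 4, clen, dtype=np.int8)  # 0=A 1=C 2=G 3=T
    cg = (bg[:-1] == 1) & (bg[1:] == 2)
    bg[1:][cg] = 3  # break background CGs (G -> T)
    cpg_start = np.zeros(clen, dtype=bool)
    occupied = np.zeros(clen, dtype=bool)

    def place(lo: int, hi: int, count: int) -> int:
        lo, hi = max(lo, 0), min(hi, clen - 1)
        span = hi - lo - 1
        if count <= 0 or span <= 2:
            return 0
        placed = 0
        for _ in range(8):
            if placed >= count:
                break
            m = min(span, 4 * (count - placed) + 16)
            cand = np.sort(rng.choice(span, size=m, replace=False) + lo)
            last = -5
            for p in cand:
                if placed >= count:
                    break
                if p <= last + 1 or occupied[p] or occupied[p + 1]:
                    continue
                occupied[p] = occupied[p + 1] = True
                cpg_start[p] = True
                last = p
                placed += 1
        return placed

    class_by_name = config.class_by_name
    # 1. CpG-island promoters
    for gene in genes:
        cls = class_by_name[meta.at[gene.gene_id, "class_name"]]
        if not cls.promoter_cpg_island:
            continue
        if gene.strand == "+":
            lo, hi = gene.tx_start - config.promoter_up, gene.tx_start + config.promoter_down
        else:
            lo, hi = gene.tx_end - config.promoter_down, gene.tx_end + config.promoter_up
        n = int(round(config.island_cpg_per_kb * (hi - lo) / 1000.0))
        place(lo, hi, n)
    # 2. gene bodies, budget net of island CpGs already inside the body
    for gene in genes:
        target = float(meta.at[gene.gene_id, "target_cpg_per_kb"])
        budget = int(round(target * gene.length / 1000.0))
        already = int(cpg_start[gene.tx_start:gene.tx_end].sum())
        place(gene.tx_start, gene.tx_end, budget - already)
    # 3. intergenic background
    edges = [0]
    for gene in genes:
        edges.extend([gene.tx_start, gene.tx_end])
    edges.append(clen)
    for lo, hi in zip(edges[::2], edges[1::2]):
        n = int(round(config.intergenic_cpg_per_kb * max(hi - lo, 0) / 1000.0))
        place(lo, hi, n)

    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = lut[bg]
    idx = np.nonzero(cpg_start)[0]
    arr[idx] = ord("C")
    arr[idx + 1] = ord("G")
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

def _gene_role_intervals(
    gene: GeneModel, config: SyntheticConfig
) -> dict[str, tuple[int, int]]:
    mid = gene.tx_start + gene.length // 2
    if gene.strand == "+":
        return {
            "flank_up": (gene.tx_start - config.flank_bp, gene.tx_start),
            "body5": (gene.tx_start, mid),
            "body3": (mid, gene.tx_end),
            "flank_down": (gene.tx_end, gene.tx_end + config.flank_bp),
            "promoter": (gene.tx_start - config.promoter_up,
                         gene.tx_start + config.promoter_down),
        }
    return {
        "flank_up": (gene.tx_end, gene.tx_end + config.flank_bp),
        "body5": (mid, gene.tx_end),
        "body3": (gene.tx_start, mid),
        "flank_down": (gene.tx_start - config.flank_bp, gene.tx_start),
        "promoter": (gene.tx_end - config.promoter_down,
                     gene.tx_end + config.promoter_up),
    }


def simulate_tracks(
    genes: Sequence[GeneModel],
    meta: pd.DataFrame,
    config: SyntheticConfig,
    condition: str,
) -> dict[str, SignalTrack]:
    """Probe-level log2 tracks for every mark in one condition.

    Each probe's target is the sum of the per-gene piecewise-constant role
    amplitudes covering its midpoint (the promoter amplitude overrides the
    gene's own body/flank amplitude near the TSS), plus Gaussian noise.
    Knockout conditions apply the class's deltas; H3K36me3 body amplitude is
    shifted by ``k36_expression_coupling`` per log2 unit of the gene's base
    expression relative to its class mean.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = config.conditions.index(condition)
    clen = chromosome_length(genes, config)
    starts = np.arange(0, clen - config.probe_length + 1, config.probe_spacing,
                       dtype=np.int64)
    mids = starts + config.probe_length // 2
    class_by_name = config.class_by_name
    base = {mark: np.zeros(len(starts)) for mark in config.marks}

    for gene in genes:
        cls = class_by_name[meta.at[gene.gene_id, "class_name"]]
        ko = cls.knockout.get(condition)
        intervals = _gene_role_intervals(gene, config)
        expr_dev = float(meta.at[gene.gene_id, "base_expression"]) - cls.expression_log2[0]
        for mark in config.marks:
            amps = cls.mark_profile(mark).amplitudes()
            if ko is not None:
                amps = ko.apply(mark, amps)
            if mark == "H3K36me3":
                for role in ("body5", "body3"):
                    if amps[role] != 0.0:
                        amps[role] += config.k36_expression_coupling * expr_dev
            if all(v == 0.0 for v in amps.values()):
                continue
            lo = min(iv[0] for iv in intervals.values())
            hi = max(iv[1] for iv in intervals.values())
            i0 = np.searchsorted(mids, lo, side="left")
            i1 = np.searchsorted(mids, hi, side="left")
            contrib = np.zeros(i1 - i0)
            for role in ("flank_up", "body5", "body3", "flank_down", "promoter"):
                s, e = intervals[role]
                j0 = np.searchsorted(mids, s, side="left") - i0
                j1 = np.searchsorted(mids, e, side="left") - i0
                contrib[j0:j1] = amps[role]  # promoter last: overrides
            base[mark][i0:i1] += contrib

    tracks = {}
    for mark_idx, mark in enumerate(config.marks):
        rng = _rng(config, _STAGE_TRACKS, cond_idx, mark_idx)
        values = base[mark] + rng.normal(0.0, config.noise_sd, len(starts))
        tracks[mark] = SignalTrack.from_arrays(
            mark, condition, config.chrom, starts, starts + config.probe_length, values
        )
    return tracks


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    genes: Sequence[GeneModel],
    meta: pd.DataFrame,
    config: SyntheticConfig,
    condition: str,
) -> tuple[pd.Series, pd.DataFrame]:
    """Gene- and exon-level log2 intensities for one condition.

    Gene value = base expression + knockout delta + Normal(0, noise); each
    exon adds independent Normal(0, exon sd) scatter.  Exons are numbered in
    transcriptional order.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = config.conditions.index(condition)
    rng = _rng(config, _STAGE_EXPR, cond_idx)
    class_by_name = config.class_by_name
    deltas = np.array(
        [
            class_by_name[c].knockout.get(condition, KnockoutEffect()).expression_delta
            for c in meta["class_name"]
        ]
    )
    gene_values = (
        meta["base_expression"].to_numpy()
        + deltas
        + rng.normal(0.0, config.expression_noise_sd, len(meta))
    )
    gene_series = pd.Series(gene_values, index=meta.index, name=condition)

    rows = []
    for gene, gval in zip(genes, gene_values):
        exons_t = gene.transcriptional_order(gene.exons)
        for ordinal, (s, e) in enumerate(exons_t, start=1):
            rows.append((f"{gene.gene_id}.e{ordinal:02d}", gene.gene_id, ordinal, s, e, gval))
    exon_df = pd.DataFrame(
        rows, columns=["exon_id", "gene_id", "ordinal", "start", "end", condition]
    ).set_index("exon_id")
    exon_df[condition] += rng.normal(0.0, config.exon_expression_sd, len(exon_df))
    return gene_series, exon_df


# ---------------------------------------------------------------------------
# Dataset orchestration and fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list[GeneModel]
    meta: pd.DataFrame
    sequence: str
    tracks: dict[str, dict[str, SignalTrack]]  # condition -> mark -> track
    expression_genes: pd.DataFrame  # gene_id x condition
    expression_exons: pd.DataFrame  # exon_id x (gene_id, ordinal, start, end, conditions)

    @property
    def genome(self) -> dict[str, str]:
        return {self.config.chrom: self.sequence}


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run all generator stages for every configured condition."""
    genes, meta = simulate_annotation(config)
    sequence = simulate_sequence(genes, meta, config)
    tracks = {
        cond: simulate_tracks(genes, meta, config, cond)
        for cond in config.conditions
    }
    gene_cols = []
    exon_frame = None
    for cond in config.conditions:
        gseries, edf = simulate_expression(genes, meta, config, cond)
        gene_cols.append(gseries)
        if exon_frame is None:
            exon_frame = edf
        else:
            exon_frame[cond] = edf[cond]
    return SyntheticDataset(
        config=config,
        genes=genes,
        meta=meta,
        sequence=sequence,
        tracks=tracks,
        expression_genes=pd.concat(gene_cols, axis=1),
        expression_exons=exon_frame,
    )


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for g in genes:
            thick = (g.cds_start, g.cds_end) if g.coding else (g.tx_start, g.tx_start)
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            offsets = ",".join(str(s - g.tx_start) for s, e in g.exons) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                        thick[0], thick[1], "0,0,0", len(g.exons), sizes, offsets,
                    )
                )
                + "\n"
            )


def write_refflat(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for g in genes:
            cds = (g.cds_start, g.cds_end) if g.coding else (g.tx_end, g.tx_end)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.symbol, g.gene_id, g.chrom, g.strand, g.tx_start,
                        g.tx_end, cds[0], cds[1], len(g.exons),
                        ",".join(str(s) for s, _ in g.exons) + ",",
                        ",".join(str(e) for _, e in g.exons) + ",",
                    )
                )
                + "\n"
            )


def _write_fasta(sequence: str, chrom: str, path: Path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


def _write_bedgraph(track: SignalTrack, path: Path) -> None:
    with open(path, "wt") as fh:
        for chrom in track.chroms:
            d = track.arrays(chrom)
            for s, e, v in zip(d["starts"], d["ends"], d["values"]):
                fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def _config_to_jsonable(config: SyntheticConfig) -> dict:
    raw = asdict(config)
    for cls in raw["classes"]:
        cls["marks"] = {m: asdict(p) if not isinstance(p, dict) else p
                        for m, p in cls["marks"].items()}
        cls["knockout"] = {
            cond: asdict(eff) if not isinstance(eff, dict) else eff
            for cond, eff in cls["knockout"].items()
        }
    return raw


def write_fixture_bundle(dataset: SyntheticDataset, outdir: str | Path) -> dict:
    """Write the dataset as standard-format files plus a manifest.

    Emits indexed FASTA, BED12 and refFlat gene models, one bedGraph per
    (mark, condition), gene/exon expression TSVs, the per-gene class table,
    and ``manifest.json`` recording the config, seed and file list.
    """
    from pyfaidx import Faidx

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(exist_ok=True)
    cfg = dataset.config

    files: dict[str, str] = {}
    fasta = out / "genome.fa"
    _write_fasta(dataset.sequence, cfg.chrom, fasta)
    Faidx(str(fasta))  # writes genome.fa.fai
    files["fasta"] = "genome.fa"
    files["fai"] = "genome.fa.fai"
    write_bed12(dataset.genes, out / "genes.bed12")
    files["bed12"] = "genes.bed12"
    write_refflat(dataset.genes, out / "genes.refflat.txt")
    files["refflat"] = "genes.refflat.txt"
    track_files: dict[str, dict[str, str]] = {}
    for cond, marks in dataset.tracks.items():
        for mark, track in marks.items():
            rel = f"tracks/{mark}.{cond}.bedGraph"
            _write_bedgraph(track, out / rel)
            track_files.setdefault(mark, {})[cond] = rel
    files["expression_genes"] = "expression.genes.tsv"
    dataset.expression_genes.to_csv(out / files["expression_genes"], sep="\t")
    files["expression_exons"] = "expression.exons.tsv"
    dataset.expression_exons.to_csv(out / files["expression_exons"], sep="\t")
    files["classes"] = "classes.tsv"
    dataset.meta.to_csv(out / files["classes"], sep="\t")

    manifest = {
        "format_version": 1,
        "seed": cfg.seed,
        "chrom": cfg.chrom,
        "conditions": list(cfg.conditions),
        "marks": list(cfg.marks),
        "files": files,
        "tracks": track_files,
        "config": _config_to_jsonable(cfg),
    }
    with open(out / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def validate_bundle(bundle_dir: str | Path) -> list[str]:
    """Check a fixture bundle against its manifest; returns all errors."""
    out = Path(bundle_dir)
    errors: list[str] = []
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        return [f"missing manifest: {manifest_path}"]
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        return [f"unreadable manifest: {exc}"]
    listed = list(manifest.get("files", {}).values())
    for tr in manifest.get("tracks", {}).values():
        listed.extend(tr.values())
    for rel in listed:
        if not (out / rel).exists():
            errors.append(f"missing file: {rel}")
    if "seed" not in manifest:
        errors.append("manifest lacks a seed")
    return errors
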