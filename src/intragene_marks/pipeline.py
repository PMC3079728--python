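"""End-to-end analysis: from a config of input paths to a structured report.

Stage order follows the analysis flow: annotations -> signal summaries ->
occupancy classification and statistics -> metagene profiles -> exon-level
and differential-expression analyses.  Every numeric in the report is
produced by one of the library operations; the provenance block records a
hash over the config and all input bytes so identical inputs yield an
identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .annotations import AnalysisParams, GeneModel, label_gene_class, read_gene_models
from .expression_analysis import (
    ExpressionCpgResult,
    classify_differential,
    exon_intron_summary,
    expression_change_vs_cpg,
    select_expression_extremes,
)
from .occupancy_stats import (
    MarkCoverageTable,
    build_coverage_table,
    chi_square_test,
    classify_marked_genes,
    cooccupancy_counts,
    group_signal_comparison,
    pearson_correlation,
)
from .profiles import (
    BinProfile,
    CompositeProfile,
    ProfileMatrix,
    bin_gene_profile,
    build_profile_matrix,
    cluster_profile_matrix,
    composite_profile,
)
from .signal_io import read_signal_track

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "PipelineError",
    "validate_config",
    "run_full_analysis",
    "run_config_from_bundle",
]

logger = logging.getLogger("intragene_marks")

DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "MIRA+H3K36me3": ("MIRA", "H3K36me3"),
    "H3K9me3+H3K36me3": ("H3K9me3", "H3K36me3"),
    "H3K27me3": ("H3K27me3",),
}

DEFAULT_CORRELATIONS: tuple[tuple[str, str, str], ...] = (
    ("gene_body", "MIRA", "H3K36me3"),
    ("gene_body", "UMC", "H3K36me3"),
    ("promoter", "UMC", "MIRA"),
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and input."""


@dataclass
class RunConfig:
    annotation: str
    tracks: dict[str, dict[str, str]]  # mark -> condition -> path
    outdir: str
    annotation_format: str = "refflat"
    fasta: str | None = None
    expression_genes: str | None = None
    expression_exons: str | None = None
    baseline_condition: str = "WT"
    knockout_condition: str | None = None
    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    znf_override: tuple[str, ...] = ()
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        params = AnalysisParams(**raw.pop("params", {}))
        groups = {k: tuple(v) for k, v in raw.pop("groups", DEFAULT_GROUPS).items()}
        return cls(params=params, groups=groups, **raw)

    def to_jsonable(self) -> dict:
        out = asdict(self)
        out["groups"] = {k: list(v) for k, v in self.groups.items()}
        out["znf_override"] = list(self.znf_override)
        return out

    def input_paths(self) -> list[Path]:
        paths = [Path(self.annotation)]
        if self.fasta:
            paths.append(Path(self.fasta))
        for conds in self.tracks.values():
            paths.extend(Path(p) for p in conds.values())
        for extra in (self.expression_genes, self.expression_exons):
            if extra:
                paths.append(Path(extra))
        return paths


def validate_config(config: RunConfig) -> list[str]:
    """Collect every config problem at once; an empty list means ok."""
    errors: list[str] = []
    for path in config.input_paths():
        if not path.exists():
            errors.append(f"missing input file: {path}")
    if config.annotation_format not in ("refflat", "bed12"):
        errors.append(f"unknown annotation format {config.annotation_format!r}")
    try:
        _ = config.params  # dataclass validated on construction
    except ValueError as exc:  # pragma: no cover - params validated earlier
        errors.append(str(exc))
    conditions = {c for conds in config.tracks.values() for c in conds}
    if config.tracks and config.baseline_condition not in conditions:
        errors.append(
            f"baseline condition {config.baseline_condition!r} has no tracks"
        )
    if config.knockout_condition and config.knockout_condition not in conditions:
        errors.append(
            f"knockout condition {config.knockout_condition!r} has no tracks"
        )
    # light format sniff of the first data line of each track
    from .signal_io import SignalParseError, _iter_bedgraph_with_header_skip

    for mark, conds in config.tracks.items():
        for cond, p in conds.items():
            path = Path(p)
            if not path.exists() or path.suffix.lower() in (".wig", ".bw", ".bigwig"):
                continue
            try:
                next(iter(_iter_bedgraph_with_header_skip(path)), None)
            except SignalParseError as exc:
                errors.append(f"track {mark}/{cond}: {exc}")
    return errors


@dataclass
class AnalysisReport:
    config: RunConfig
    coverage: MarkCoverageTable
    marked: pd.DataFrame  # genes x marks (boolean, baseline condition)
    cooccupancy: dict[str, dict]
    correlations: dict[str, dict]
    group_members: dict[str, tuple[str, ...]]
    composites: dict[str, CompositeProfile]  # "group|mark"
    heatmap: ProfileMatrix | None
    group_comparison: pd.DataFrame | None
    exon_strata: pd.DataFrame | None
    exon_signal: pd.DataFrame | None
    differential: pd.DataFrame | None
    expression_cpg: ExpressionCpgResult | None
    provenance: dict

    def summary(self) -> dict:
        out: dict[str, Any] = {
            "provenance": self.provenance,
            "n_genes": int(len(self.coverage.gene_ids)),
            "cooccupancy": self.cooccupancy,
            "correlations": self.correlations,
            "groups": {k: len(v) for k, v in self.group_members.items()},
        }
        if self.expression_cpg is not None:
            c = self.expression_cpg.correlation
            out["expression_change_vs_cpg"] = {"r": c.r, "p": c.p, "n": c.n}
        if self.differential is not None:
            out["differential_counts"] = (
                self.differential["status"].value_counts(dropna=True).to_dict()
            )
        return out


def _provenance(config: RunConfig) -> dict:
    h = hashlib.sha256()
    h.update(json.dumps(config.to_jsonable(), sort_keys=True).encode())
    for path in sorted(config.input_paths()):
        h.update(str(path).encode())
        h.update(path.read_bytes())
    return {"config_hash": h.hexdigest(), "version": __version__}


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_config_from_bundle(
    bundle_dir: str | Path, outdir: str | Path, **overrides
) -> RunConfig:
    """Build a RunConfig pointing at a synthetic fixture bundle."""
    bundle = Path(bundle_dir)
    manifest = json.loads((bundle / "manifest.json").read_text())
    tracks = {
        mark: {cond: str(bundle / rel) for cond, rel in conds.items()}
        for mark, conds in manifest["tracks"].items()
    }
    conditions = manifest["conditions"]
    kwargs: dict[str, Any] = dict(
        annotation=str(bundle / manifest["files"]["refflat"]),
        annotation_format="refflat",
        fasta=str(bundle / manifest["files"]["fasta"]),
        tracks=tracks,
        expression_genes=str(bundle / manifest["files"]["expression_genes"]),
        expression_exons=str(bundle / manifest["files"]["expression_exons"]),
        baseline_condition=conditions[0],
        knockout_condition=conditions[1] if len(conditions) > 1 else None,
        outdir=str(outdir),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def run_full_analysis(config: RunConfig, write: bool = True) -> AnalysisReport:
    """Execute every analysis stage and (optionally) write the report files."""
    errors = validate_config(config)
    if errors:
        raise PipelineError("config validation failed: " + "; ".join(errors))
    params = config.params
    outdir = Path(config.outdir)
    log_handler = None
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "composites").mkdir(exist_ok=True)
        log_handler = logging.FileHandler(outdir / "run.log")
        log_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(log_handler)

    # -- annotations --------------------------------------------------------
    genes = _stage("annotations")(read_gene_models)(
        config.annotation, config.annotation_format
    )
    genes = label_gene_class(genes, override_list=config.znf_override)
    logger.info("annotations: %d transcripts", len(genes))
    genome = None
    if config.fasta:
        from pyfaidx import Fasta

        genome = Fasta(config.fasta)

    # -- signal summaries ---------------------------------------------------
    @_stage("signal_io")
    def _read_tracks():
        out = []
        for mark, conds in config.tracks.items():
            for cond, path in conds.items():
                out.append(read_signal_track(path, mark=mark, condition=cond))
        return out

    tracks = _read_tracks()
    baseline_tracks = [t for t in tracks if t.condition == config.baseline_condition]
    coverage = _stage("coverage")(build_coverage_table)(
        genes, tracks, params, genome=genome
    )
    logger.info(
        "coverage: %d genes x %d tracks", len(coverage.gene_ids), len(tracks)
    )

    # -- occupancy classification and statistics ----------------------------
    marks = sorted({t.mark for t in baseline_tracks})
    marked = pd.DataFrame(
        {
            m: classify_marked_genes(coverage, m, params, config.baseline_condition)
            for m in marks
        }
    )
    for m in marks:
        excluded = int(marked[m].isna().sum())
        logger.info(
            "classification %s: %d marked / %d excluded (no probes)",
            m, int(marked[m].fillna(False).sum()), excluded,
        )

    cooccupancy: dict[str, dict] = {}
    pairs = [("MIRA", "H3K36me3"), ("H3K9me3", "H3K36me3"), ("H3K27me3", "MIRA")]
    for a, b in pairs:
        if a not in marked.columns or b not in marked.columns:
            continue
        counts = cooccupancy_counts(marked[a], marked[b])
        entry = counts.as_dict()
        try:
            chi = chi_square_test(counts.table)
            entry["chi_square"] = {"statistic": chi.statistic, "df": chi.df, "p": chi.p}
        except ValueError as exc:
            entry["chi_square"] = {"error": str(exc)}
        cooccupancy[f"{a}|{b}"] = entry

    corr_params = AnalysisParams(
        **{**asdict(params), "min_probes": params.min_probes_corr}
    )
    correlations: dict[str, dict] = {}
    for role, a, b in DEFAULT_CORRELATIONS:
        if a not in config.tracks or b not in config.tracks:
            continue
        if config.baseline_condition not in config.tracks[a]:
            continue
        tab = coverage if role == "gene_body" else build_coverage_table(
            genes,
            [t for t in baseline_tracks if t.mark in (a, b)],
            corr_params,
            region_role=role,
        )
        try:
            res = pearson_correlation(
                tab.mean_signal[(a, config.baseline_condition)],
                tab.mean_signal[(b, config.baseline_condition)],
            )
            correlations[f"{role}:{a}~{b}"] = {"r": res.r, "p": res.p, "n": res.n}
        except ValueError as exc:
            correlations[f"{role}:{a}~{b}"] = {"error": str(exc)}

    # -- gene groups by mark combination ------------------------------------
    group_members: dict[str, tuple[str, ...]] = {}
    for name, combo in config.groups.items():
        if not all(m in marked.columns for m in combo):
            continue
        mask = pd.Series(True, index=marked.index)
        for m in combo:
            mask &= marked[m].fillna(False).astype(bool)
        group_members[name] = tuple(marked.index[mask])
        logger.info("group %s: %d genes", name, int(mask.sum()))

    # -- metagene profiles ---------------------------------------------------
    @_stage("profiles")
    def _profiles():
        by_gene = {g.gene_id: g for g in genes}
        profs: dict[str, dict[str, BinProfile]] = {}
        for track in baseline_tracks:
            profs[track.mark] = {
                g.gene_id: bin_gene_profile(g, track, params)
                for g in genes
                if g.length >= params.n_body_bins
            }
        composites: dict[str, CompositeProfile] = {}
        for gname, members in group_members.items():
            for mark, per_gene in profs.items():
                chosen = [per_gene[gid] for gid in members if gid in per_gene]
                if chosen:
                    composites[f"{gname}|{mark}"] = composite_profile(chosen, gname)
        return profs, composites

    profs, composites = _profiles()

    heatmap = None
    if len(genes) >= 2:
        matrix = build_profile_matrix(genes, baseline_tracks, params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            heatmap = cluster_profile_matrix(matrix)

    # -- group comparison of gene-body methylation ---------------------------
    group_comparison = None
    mira_key = ("MIRA", config.baseline_condition)
    if "MIRA" in config.tracks and len(group_members) >= 2:
        groups_values = {}
        for gname, members in group_members.items():
            vals = coverage.mean_signal.loc[list(members), mira_key].dropna()
            if len(vals) >= 2:
                groups_values[gname] = vals.to_numpy()
        if len(groups_values) >= 2:
            group_comparison = group_signal_comparison(groups_values)

    # -- exon-level analysis --------------------------------------------------
    exon_strata = exon_signal = None
    if config.expression_exons:
        @_stage("exon_analysis")
        def _exons():
            exons = pd.read_csv(config.expression_exons, sep="\t", index_col=0)
            focus = set(group_members.get("MIRA+H3K36me3", ())) or set(
                coverage.gene_ids
            )
            exons_f = exons[exons["gene_id"].isin(focus)]
            strata = select_expression_extremes(
                exons_f[config.baseline_condition], params
            )
            k36 = next(
                (t for t in baseline_tracks if t.mark == "H3K36me3"), None
            )
            rows = []
            if k36 is not None:
                from .annotations import Region
                from .signal_io import assign_probe_values

                by_gene = {g.gene_id: g for g in genes}
                for exon_id, row in exons_f.iterrows():
                    gene = by_gene[row["gene_id"]]
                    region = Region(gene.chrom, int(row["start"]), int(row["end"]),
                                    gene.strand, "exon")
                    values = assign_probe_values(k36, region, params)
                    rows.append(
                        {
                            "exon_id": exon_id,
                            "gene_id": row["gene_id"],
                            "stratum": strata.strata.get(exon_id),
                            "mean_H3K36me3": float(values.mean()) if len(values) else np.nan,
                            "n_probes": len(values),
                        }
                    )
            strata_df = strata.strata.rename("stratum").to_frame()
            signal_df = pd.DataFrame(rows).set_index("exon_id") if rows else None
            return strata_df, signal_df

        exon_strata, exon_signal = _exons()

    # -- differential expression vs CpG density -------------------------------
    differential = None
    expression_cpg = None
    if config.expression_genes and config.knockout_condition:
        @_stage("differential")
        def _diff():
            expr = pd.read_csv(config.expression_genes, sep="\t", index_col=0)
            diff = classify_differential(
                expr, config.baseline_condition, config.knockout_condition, params
            )
            result = None
            if "cpg_body_per_kb" in coverage.meta.columns:
                result = expression_change_vs_cpg(
                    diff["delta"],
                    coverage.meta["cpg_body_per_kb"],
                    coverage.meta["znf"],
                )
            return diff, result

        differential, expression_cpg = _diff()
        logger.info(
            "differential: %s",
            differential["status"].value_counts(dropna=True).to_dict(),
        )

    report = AnalysisReport(
        config=config,
        coverage=coverage,
        marked=marked,
        cooccupancy=cooccupancy,
        correlations=correlations,
        group_members=group_members,
        composites=composites,
        heatmap=heatmap,
        group_comparison=group_comparison,
        exon_strata=exon_strata,
        exon_signal=exon_signal,
        differential=differential,
        expression_cpg=expression_cpg,
        provenance=_provenance(config),
    )
    if write:
        _write_report(report, outdir)
    if log_handler is not None:
        logger.removeHandler(log_handler)
        log_handler.close()
    return report


def _write_report(report: AnalysisReport, outdir: Path) -> None:
    report.coverage.to_tsv(outdir / "coverage.tsv")
    report.marked.to_csv(outdir / "marked.tsv", sep="\t")
    for key, comp in report.composites.items():
        safe = key.replace("|", ".").replace("+", "_")
        comp.to_frame().to_csv(outdir / "composites" / f"{safe}.tsv",
                               sep="\t", index=False)
    if report.heatmap is not None:
        flat = report.heatmap.data.copy()
        flat.columns = [f"{m}:{b}" for m, b in flat.columns]
        flat.to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
    if report.group_comparison is not None:
        report.group_comparison.to_csv(outdir / "group_comparison.tsv",
                                       sep="\t", index=False)
    if report.exon_strata is not None:
        report.exon_strata.to_csv(outdir / "exon_strata.tsv", sep="\t")
    if report.exon_signal is not None:
        report.exon_signal.to_csv(outdir / "exon_signal.tsv", sep="\t")
    if report.differential is not None:
        report.differential.to_csv(outdir / "differential.tsv", sep="\t")
    if report.expression_cpg is not None:
        report.expression_cpg.scatter.to_csv(
            outdir / "expression_cpg_scatter.tsv", sep="\t"
        )
    with open(outdir / "report.json", "wt") as fh:
        json.dump(report.summary(), fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
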