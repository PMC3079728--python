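"""Synthetic-data generator: determinism, planted structure, round-trips."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from intragene_marks import (
    Region,
    cpg_density,
    derive_regions,
    flagship_config,
    label_gene_class,
    pearson_correlation,
    read_gene_models,
    read_signal_track,
    region_mean_signal,
    simulate_annotation,
    simulate_dataset,
    simulate_expression,
    simulate_sequence,
    simulate_tracks,
    validate_bundle,
    write_fixture_bundle,
)
from intragene_marks.synthetic_data import _class_counts


def dir_digest(path: Path) -> dict:
    out = {}
    for p in sorted(path.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(path))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


class TestAnnotation:
    def test_determinism(self):
        cfg = flagship_config(seed=7, n_genes=100)
        genes_a, meta_a = simulate_annotation(cfg)
        genes_b, meta_b = simulate_annotation(cfg)
        assert genes_a == genes_b
        pd.testing.assert_frame_equal(meta_a, meta_b)

    def test_class_counts_match_proportions_within_3_sigma(self):
        cfg = flagship_config(seed=1)
        _, meta = simulate_annotation(cfg)
        counts = meta["class_name"].value_counts()
        for cls in cfg.classes:
            expected = cls.proportion * cfg.n_genes
            sigma = np.sqrt(cfg.n_genes * cls.proportion * (1 - cls.proportion))
            assert abs(counts[cls.name] - expected) <= 3 * sigma
        assert _class_counts(cfg).sum() == cfg.n_genes

    def test_znf_class_symbols_match_labelling_rule(self, mini):
        labelled = label_gene_class(mini.genes)
        znf_ids = set(mini.meta.index[mini.meta.class_name == "ZNF_LIKE"])
        for g in labelled:
            assert (g.gene_id in znf_ids) == ("ZNF" in g.labels)

    def test_exon_structure_valid(self, mini):
        for g in mini.genes:
            assert g.exons[0][0] == g.tx_start and g.exons[-1][1] == g.tx_end
            assert 2 <= len(g.exons) <= 12
            assert g.length % 20 == 0


class TestSequence:
    def test_realized_body_density_tracks_target(self, mini):
        genome = mini.genome
        for gene in mini.genes:
            body = derive_regions(gene)["gene_body"]
            seq = genome[gene.chrom][body.start:body.end]
            realized = cpg_density(seq, body)
            target = mini.meta.at[gene.gene_id, "target_cpg_per_kb"]
            assert realized == pytest.approx(target, rel=0.15, abs=0.5)

    def test_zero_target_class_has_no_cpg(self):
        from dataclasses import replace
        cfg = flagship_config(seed=5, n_genes=12)
        bare = tuple(
            replace(c, body_cpg_per_kb=(0.0, 0.0), promoter_cpg_island=False)
            for c in cfg.classes
        )
        cfg = flagship_config(seed=5, n_genes=12, classes=bare,
                              intergenic_cpg_per_kb=0.0)
        genes, meta = simulate_annotation(cfg)
        seq = simulate_sequence(genes, meta, cfg)
        assert "CG" not in seq

    def test_island_promoters_denser_than_bodies(self, mini):
        genome = mini.genome
        meth = [g for g in mini.genes
                if mini.meta.at[g.gene_id, "class_name"] == "METH_ACTIVE"][:20]
        for gene in meth:
            prom = derive_regions(gene)["promoter"]
            seq = genome[gene.chrom][prom.start:prom.end]
            assert cpg_density(seq, prom) > 2 * mini.meta.at[
                gene.gene_id, "target_cpg_per_kb"]

    def test_fixed_seed_identical_sequence(self):
        cfg = flagship_config(seed=9, n_genes=20)
        genes, meta = simulate_annotation(cfg)
        assert simulate_sequence(genes, meta, cfg) == simulate_sequence(genes, meta, cfg)


class TestTracks:
    @pytest.fixture(scope="class")
    def noiseless(self):
        cfg = flagship_config(seed=3, n_genes=40, noise_sd=0.0,
                              k36_expression_coupling=0.0)
        genes, meta = simulate_annotation(cfg)
        return cfg, genes, meta, simulate_tracks(genes, meta, cfg, "WT")

    def body3_region(self, gene):
        """3' half of the body: avoids the promoter-overridden 5' end."""
        mid = gene.tx_start + gene.length // 2
        if gene.strand == "+":
            return Region(gene.chrom, mid, gene.tx_end, gene.strand, "gene_body")
        return Region(gene.chrom, gene.tx_start, mid, gene.strand, "gene_body")

    def test_meth_active_targets_exact_at_zero_noise(self, noiseless):
        cfg, genes, meta, tracks = noiseless
        for gene in genes:
            if meta.at[gene.gene_id, "class_name"] != "METH_ACTIVE":
                continue
            assert region_mean_signal(tracks["MIRA"], self.body3_region(gene)) == 2.0
            prom = derive_regions(gene)["promoter"]
            assert region_mean_signal(tracks["MIRA"], prom) == -1.0

    def test_znf_dual_occupancy_planted(self, noiseless):
        cfg, genes, meta, tracks = noiseless
        znf = [g for g in genes if meta.at[g.gene_id, "class_name"] == "ZNF_LIKE"]
        assert znf
        for gene in znf:
            body3 = self.body3_region(gene)
            assert region_mean_signal(tracks["H3K9me3"], body3) > 1.0
            assert region_mean_signal(tracks["H3K36me3"], body3) > 1.0

    def test_knockout_scales_body_methylation(self, noiseless):
        cfg, genes, meta, _ = noiseless
        dko = simulate_tracks(genes, meta, cfg, "DKO")
        for gene in genes:
            if meta.at[gene.gene_id, "class_name"] != "METH_ACTIVE":
                continue
            assert region_mean_signal(dko["MIRA"], self.body3_region(gene)) \
                == pytest.approx(0.8)

    def test_promoter_umc_anticorrelated_with_mira(self, mini):
        tracks = mini.tracks["WT"]
        umc, mira = [], []
        for gene in mini.genes:
            prom = derive_regions(gene)["promoter"]
            u = region_mean_signal(tracks["UMC"], prom)
            m = region_mean_signal(tracks["MIRA"], prom)
            if u is not None and m is not None:
                umc.append(u)
                mira.append(m)
        assert pearson_correlation(umc, mira).r < 0


class TestExpression:
    def test_knockout_activates_znf(self, mini):
        wt = mini.expression_genes["WT"]
        dko = mini.expression_genes["DKO"]
        delta = dko - wt
        znf = mini.meta.class_name == "ZNF_LIKE"
        assert (delta[znf.to_numpy()] >= 0.5).mean() >= 0.95
        assert (delta[(~znf).to_numpy()].abs() >= 0.5).mean() <= 0.05

    def test_exon_values_scatter_around_gene_value(self, mini):
        exons = mini.expression_exons
        merged = exons.join(mini.expression_genes["WT"].rename("gene_WT"),
                            on="gene_id")
        resid = merged["WT"] - merged["gene_WT"]
        assert abs(resid.mean()) < 0.05
        assert 0.2 < resid.std() < 0.4

    def test_fixed_seed_identical_table(self):
        cfg = flagship_config(seed=21, n_genes=25)
        genes, meta = simulate_annotation(cfg)
        a = simulate_expression(genes, meta, cfg, "WT")
        b = simulate_expression(genes, meta, cfg, "WT")
        pd.testing.assert_series_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestBundle:
    @pytest.fixture(scope="class")
    def bundle(self, tmp_path_factory):
        cfg = flagship_config(seed=17, n_genes=30)
        ds = simulate_dataset(cfg)
        out = tmp_path_factory.mktemp("bundle")
        manifest = write_fixture_bundle(ds, out)
        return ds, out, manifest

    def test_byte_identical_regeneration(self, bundle, tmp_path):
        ds, out, _ = bundle
        ds2 = simulate_dataset(flagship_config(seed=17, n_genes=30))
        write_fixture_bundle(ds2, tmp_path / "again")
        assert dir_digest(out) == dir_digest(tmp_path / "again")

    def test_round_trip_through_package_readers(self, bundle):
        ds, out, manifest = bundle
        genes = read_gene_models(out / "genes.refflat.txt", "refflat")
        assert genes == ds.genes
        bed_genes = read_gene_models(out / "genes.bed12", "bed12")
        assert [(g.tx_start, g.tx_end, tuple(g.exons)) for g in bed_genes] == \
            [(g.tx_start, g.tx_end, tuple(g.exons)) for g in ds.genes]
        track = read_signal_track(out / "tracks" / "MIRA.WT.bedGraph",
                                  mark="MIRA", condition="WT")
        orig = ds.tracks["WT"]["MIRA"].arrays(ds.config.chrom)
        got = track.arrays(ds.config.chrom)
        np.testing.assert_array_equal(got["starts"], orig["starts"])
        np.testing.assert_array_equal(got["values"], orig["values"])
        fasta = Fasta(str(out / "genome.fa"))
        assert str(fasta[ds.config.chrom][:]) == ds.sequence
        expr = pd.read_csv(out / "expression.genes.tsv", sep="\t", index_col=0)
        pd.testing.assert_frame_equal(expr, ds.expression_genes,
                                      check_names=False)

    def test_manifest_seed_and_validation(self, bundle):
        ds, out, manifest = bundle
        assert manifest["seed"] == ds.config.seed
        assert validate_bundle(out) == []
        victim = out / "tracks" / "H3ac.WT.bedGraph"
        victim.rename(victim.with_suffix(".bak"))
        errors = validate_bundle(out)
        victim.with_suffix(".bak").rename(victim)
        assert any("H3ac.WT.bedGraph" in e for e in errors)
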