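"""Synthetic-data generator: determinism, composition targets, error models."""

import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

import circulome as c
from circulome._seq import rotate
from circulome.simulate import ConfigurationError, truth_to_bed


class TestBuildGenome:
    def test_deterministic_byte_identical_fasta(self, tmp_path):
        cfg = c.GenomeConfig()
        for i in (1, 2):
            c.build_genome(cfg, seed=7).to_fasta(tmp_path / f"g{i}.fa")
        assert (tmp_path / "g1.fa").read_bytes() == (tmp_path / "g2.fa").read_bytes()

    def test_window_count_from_chromosome_length(self, genome):
        # 2 Mbp chromosomes tile into four 500 kbp windows each
        assert genome.n_windows("chr1") == 4
        assert genome.n_windows("chr2") == 4

    def test_short_chromosome_rejected(self):
        cfg = c.GenomeConfig(chromosomes=(("chr1", 900_000),), window_size=500_000)
        with pytest.raises(ConfigurationError, match="window"):
            c.build_genome(cfg, seed=0)

    def test_gff3_has_one_feature_per_gene(self, genome, tmp_path):
        path = tmp_path / "genes.gff3"
        genome.genes_to_gff3(path)
        features = [l for l in path.read_text().splitlines() if "\tgene\t" in l]
        assert len(features) == len(genome.gene_models) == c.GenomeConfig().n_genes

    def test_annotations_within_chromosomes(self, genome):
        sizes = genome.chrom_sizes()
        for df in (genome.gene_models, genome.trna_sites, genome.ori_sites,
                   genome.hotspot_intervals):
            for row in df.itertuples(index=False):
                assert 0 <= row.start < row.end <= sizes[row.chrom]

    def test_hotspot_contains_tandem_and_inverted_repeat(self, genome):
        hs = genome.hotspot_intervals.iloc[0]
        region = genome.sequence(hs["chrom"])[hs["start"] : hs["end"]]
        matches = c.self_dotplot(region, k=15)
        assert (matches["orientation"] == "direct").any()
        assert (matches["orientation"] == "inverted").any()


class TestSampleEccdna:
    def test_zero_gene_fraction_forces_no_gene_overlap(self, genome):
        profile = c.EccProfile(condition="D0", gene_fraction=0.0, trna_fraction=0.0,
                               ori_fraction=0.0, mean_length=1000, max_length=5000)
        _, truth = c.sample_eccdna(genome, profile, 300, seed=3)
        trees = {}
        for g in genome.gene_models.itertuples(index=False):
            trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
        for row in truth.ecc_truth.itertuples(index=False):
            assert not trees.get(row.chrom, IntervalTree()).overlap(row.start, row.end)
            assert row.genes == ""

    def test_circles_are_contiguous_genome_excisions(self, genome):
        circles, truth = c.sample_eccdna(
            genome, c.EccProfile(condition="D0", mean_length=500, max_length=2000), 20, seed=5
        )
        for circ, row in zip(circles, truth.ecc_truth.itertuples(index=False)):
            assert circ.sequence == genome.sequence(row.chrom)[row.start : row.end]

    def test_hotspot_enrichment_matches_sampler_weights(self, genome):
        profile = c.EccProfile(condition="D0", gene_fraction=0, trna_fraction=0,
                               ori_fraction=0, hotspot_enrichment=10.0,
                               mean_length=300, max_length=1000)
        weights = c.simulate.background_window_weights(genome, profile)
        assert weights["weight"].max() == 10.0
        n = 1000
        _, truth = c.sample_eccdna(genome, profile, n, seed=9)
        counts = c.assign_windows(
            truth_to_bed(truth.ecc_truth), genome.chrom_sizes(), genome.window_size
        )
        merged = counts.merge(weights, on=["chrom", "index", "start", "end"])
        hot = merged[merged["weight"] == 10.0]["count"].sum()
        expected_hot = n * 10.0 / merged["weight"].sum()
        # multinomial expectation from the sampler's own weights
        assert hot == pytest.approx(expected_hot, rel=0.25)
        nonhot_mean = merged[merged["weight"] == 1.0]["count"].mean()
        assert hot / nonhot_mean == pytest.approx(10.0, rel=0.3)

    def test_mean_length_tracks_profile(self, day0_circles_5000):
        _, truth = day0_circles_5000
        assert truth["length"].mean() == pytest.approx(4063, rel=0.05)
        assert truth["length"].between(21, 24_309).all()

    def test_oversized_circles_rejected(self, genome):
        profile = c.EccProfile(condition="D0", max_length=10_000_000)
        with pytest.raises(ConfigurationError, match="length"):
            c.sample_eccdna(genome, profile, 5, seed=0)

    def test_determinism(self, genome):
        p = c.CONDITION_PROFILES["C12"]
        t1 = c.sample_eccdna(genome, p, 50, seed=4)[1].ecc_truth
        t2 = c.sample_eccdna(genome, p, 50, seed=4)[1].ecc_truth
        pd.testing.assert_frame_equal(t1, t2)


class TestRcaReads:
    def test_exact_three_pass_read_is_tiled_circle(self):
        circle = c.EccRecord("e1", "ACGTACGTAA")
        reads, truth = c.simulate_rca_reads(
            [circle], pass_range=(3.0, 3.0), err=c.ErrorModel(0, 0), seed=2
        )
        read = reads[0][1]
        assert len(read) == 30
        phase = int(truth.read_truth.iloc[0]["phase"])
        assert read == (rotate(circle.sequence, phase) * 3)

    def test_fractional_passes_truncate_read_length(self):
        circle = c.EccRecord("e1", "ACGT" * 25)  # 100 bp
        reads, _ = c.simulate_rca_reads(
            [circle], pass_range=(2.5, 2.5), err=c.ErrorModel(0, 0), seed=2
        )
        assert len(reads[0][1]) == 250

    def test_substitution_rate_recovered(self, genome):
        profile = c.EccProfile(condition="D0", mean_length=2000, max_length=4000)
        circles, _ = c.sample_eccdna(genome, profile, 100, seed=6)
        reads, truth = c.simulate_rca_reads(
            circles, pass_range=(3.0, 3.0), err=c.ErrorModel(0.01, 0.0), seed=6
        )
        mismatches = bases = 0
        by_id = {x.ecc_id: x.sequence for x in circles}
        for (rid, seq), row in zip(reads, truth.read_truth.itertuples(index=False)):
            template = rotate(by_id[row.ecc_id], int(row.phase))
            clean = (template * (len(seq) // len(template) + 2))[: len(seq)]
            mismatches += sum(a != b for a, b in zip(seq, clean))
            bases += len(seq)
        assert mismatches / bases == pytest.approx(0.01, rel=0.2)

    def test_empty_circle_list_warns(self):
        with pytest.warns(UserWarning, match="no circles"):
            reads, truth = c.simulate_rca_reads([], seed=0)
        assert reads == [] and len(truth.read_truth) == 0

    def test_error_rates_validated(self):
        with pytest.raises(ConfigurationError):
            c.ErrorModel(substitution=0.5)


class TestRnaseqCounts:
    def test_null_plan_estimates_near_zero(self, genome_many_genes):
        plan = c.default_de_plan(genome_many_genes, seed=0, n_loss=0, n_gain_c12=0,
                                 n_gain_st12=0, base_mean=500, dispersion=0.02)
        counts, _ = c.simulate_rnaseq_counts(genome_many_genes, plan, seed=0)
        d0 = counts[[x for x in counts.columns if x.startswith("D0_")]]
        c12 = counts[[x for x in counts.columns if x.startswith("C12_")]]
        est = c.log2fc(d0, c12)["log2fc"]
        assert (est.abs() < 0.5).mean() >= 0.95

    def test_planted_twofold_effect_recovered(self, genome_many_genes):
        plan = c.default_de_plan(genome_many_genes, seed=1, n_loss=0, n_gain_c12=10,
                                 n_gain_st12=0, base_mean=1000, dispersion=0.05,
                                 effect_range=(2.0, 2.0))
        counts, truth = c.simulate_rnaseq_counts(genome_many_genes, plan, seed=1)
        d0 = counts[[x for x in counts.columns if x.startswith("D0_")]]
        c12 = counts[[x for x in counts.columns if x.startswith("C12_")]]
        est = c.log2fc(d0, c12)["log2fc"]
        planted = truth.de_truth.set_index("gene_id")["log2fc_C12"]
        recovered = est[planted[planted == 2.0].index]
        assert 1.5 <= recovered.mean() <= 2.5
        assert (recovered.between(1.2, 2.8)).all()

    def test_invalid_replicates_and_means_rejected(self, genome):
        plan = c.default_de_plan(genome, seed=0)
        with pytest.raises(ConfigurationError, match="replicates"):
            c.simulate_rnaseq_counts(genome, plan, {"D0": 0}, seed=0)
        bad = plan.copy()
        bad.loc[0, "base_mean"] = -5
        with pytest.raises(ConfigurationError, match="negative"):
            c.simulate_rnaseq_counts(genome, bad, seed=0)


class TestPlantSnps:
    @pytest.fixture(scope="module")
    def gene_circles(self, genome):
        profile = c.EccProfile(condition="ST12", gene_fraction=0.5, trna_fraction=0,
                               ori_fraction=0, mean_length=2000, max_length=6000)
        circles, truth = c.sample_eccdna(genome, profile, 40, seed=8)
        return circles, truth.ecc_truth

    def test_zero_snps_leaves_circles_untouched(self, genome, gene_circles):
        circles, truth = gene_circles
        modified, pileup, _ = c.plant_ecc_snps(genome, circles, truth, 0, seed=1)
        assert [m.sequence for m in modified] == [x.sequence for x in circles]
        assert len(pileup) == 0

    def test_planted_sites_differ_from_reference(self, genome, gene_circles):
        circles, truth = gene_circles
        modified, pileup, t = c.plant_ecc_snps(genome, circles, truth, 5, seed=2)
        snp = t.snp_truth
        assert len(snp) == 5
        assert (snp["ref_base"] != snp["ecc_base"]).all()
        for row in snp.itertuples(index=False):
            # 1-based position carries the genome (reference) base
            assert genome.sequence(row.chrom)[row.pos - 1] == row.ref_base

    def test_excessive_k_reports_shortfall(self, genome, gene_circles):
        circles, truth = gene_circles
        with pytest.raises(ValueError, match="eligible"):
            c.plant_ecc_snps(genome, circles, truth, 10_000_000, seed=0)
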