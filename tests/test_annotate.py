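"""Repeat masking, motif hits, gene content and summary arithmetic."""

import numpy as np
import pandas as pd
import pytest

import circulome as c
from circulome.annotate import (
    ConditionSummary,
    annotate_genes,
    find_motifs,
    gene_sets_by_condition,
    mask_repeats,
    summarize_condition,
)
from circulome.deconcat import EccRecord
from conftest import mutate, random_circle


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


class TestMaskRepeats:
    def test_exact_planted_copy_masked_fully(self, rng):
        motif = random_circle(rng, 200)
        library = pd.DataFrame([{"name": "LINE_0", "cls": "LINE", "sequence": motif}])
        seq = random_circle(rng, 300) + motif + random_circle(rng, 300)
        masked, intervals = mask_repeats(seq, library)
        assert intervals["bp"].sum() == 200
        assert set(intervals["cls"]) == {"LINE"}
        assert masked[300:500] == motif.lower()
        assert masked[:300].isupper() and masked[500:].isupper()

    def test_motif_free_sequence_unmasked(self, rng):
        library = pd.DataFrame(
            [{"name": "SINE_0", "cls": "SINE", "sequence": random_circle(rng, 300)}]
        )
        seq = random_circle(rng, 2000)
        masked, intervals = mask_repeats(seq, library)
        assert intervals.empty and masked == seq

    def test_overlapping_same_class_hits_merge(self, rng):
        # two exact library motifs overlapping in the target merge into
        # one run of masked bases (interval union, no double counting)
        target = random_circle(rng, 150)
        library = pd.DataFrame(
            [
                {"name": "LTR_0", "cls": "LTR", "sequence": target[10:60]},
                {"name": "LTR_1", "cls": "LTR", "sequence": target[40:90]},
            ]
        )
        masked, intervals = mask_repeats(target, library)
        assert intervals["bp"].sum() == 80  # union of [10,60) and [40,90)
        assert intervals["start"].min() == 10 and intervals["end"].max() == 90

    def test_cross_class_precedence_is_additive(self, rng):
        target = random_circle(rng, 200)
        library = pd.DataFrame(
            [
                {"name": "LINE_0", "cls": "LINE", "sequence": target[50:150]},
                {"name": "simple_0", "cls": "simple", "sequence": target[100:180]},
            ]
        )
        masked, intervals = mask_repeats(target, library)
        total = intervals["bp"].sum()
        assert total == 130  # [50,180) once, no double count
        per_class = intervals.groupby("cls")["bp"].sum()
        assert per_class["LINE"] == 100  # LINE outranks simple on the overlap
        assert per_class["simple"] == 30

    def test_wrapped_hit_across_circle_origin(self, rng):
        motif = random_circle(rng, 60)
        library = pd.DataFrame([{"name": "SINE_0", "cls": "SINE", "sequence": motif}])
        # motif split across the ends of the (circular) sequence
        seq = motif[30:] + random_circle(rng, 400) + motif[:30]
        _, intervals = mask_repeats(seq, library)
        assert intervals["bp"].sum() == 60

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mask_repeats("", pd.DataFrame([{"name": "x", "cls": "LINE", "sequence": "ACGT"}]))


class TestFindMotifs:
    def test_exact_hit_full_identity(self, rng):
        motif = random_circle(rng, 120)
        db = pd.DataFrame([{"name": "ORI_0", "sequence": motif}])
        seq = random_circle(rng, 500) + motif + random_circle(rng, 500)
        hits = find_motifs(seq, db, min_identity=0.95)
        assert len(hits) == 1
        assert hits.iloc[0]["identity"] == 1.0
        assert hits.iloc[0]["start"] == 500

    def test_divergence_above_threshold_rejected(self, rng):
        motif = random_circle(rng, 120)
        db = pd.DataFrame([{"name": "ORI_0", "sequence": motif}])
        diverged = mutate(motif, round(0.06 * 120), rng)  # 6% divergence
        seq = random_circle(rng, 300) + diverged + random_circle(rng, 300)
        assert find_motifs(seq, db, min_identity=0.95).empty

    def test_slight_divergence_scored_by_alignment(self, rng):
        motif = random_circle(rng, 120)
        db = pd.DataFrame([{"name": "ORI_0", "sequence": motif}])
        n_subs = round(0.03 * 120)
        seq = random_circle(rng, 300) + mutate(motif, n_subs, rng) + random_circle(rng, 300)
        hits = find_motifs(seq, db, min_identity=0.95)
        assert len(hits) == 1
        assert hits.iloc[0]["identity"] == pytest.approx(1 - n_subs / 120, abs=1e-3)

    def test_reverse_strand_hit_found(self, rng):
        from circulome._seq import revcomp

        motif = random_circle(rng, 80)
        db = pd.DataFrame([{"name": "tRNA_0", "sequence": motif}])
        seq = random_circle(rng, 200) + revcomp(motif) + random_circle(rng, 200)
        hits = find_motifs(seq, db, min_identity=0.90)
        assert len(hits) == 1 and hits.iloc[0]["strand"] == "-"


class TestAnnotateGenes:
    GENES = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 1000, "end": 2000, "gene_id": "gA"},
            {"chrom": "chr1", "start": 2100, "end": 3000, "gene_id": "gB"},
        ]
    )

    def placements(self, rows):
        return pd.DataFrame(
            [{"chrom": ch, "start": s, "end": e, "name": n} for n, ch, s, e in rows]
        )

    def test_placement_inside_gene(self):
        hits = annotate_genes(self.placements([("e1", "chr1", 1200, 1400)]), self.GENES)
        assert hits.iloc[0]["genes"] == "gA"

    def test_placement_spanning_two_genes(self):
        hits = annotate_genes(self.placements([("e1", "chr1", 1950, 2150)]), self.GENES)
        assert hits.iloc[0]["genes"] == "gA,gB" and hits.iloc[0]["n_genes"] == 2

    def test_one_bp_overlap_counts_as_fragment(self):
        hits = annotate_genes(self.placements([("e1", "chr1", 1999, 2050)]), self.GENES)
        assert hits.iloc[0]["genes"] == "gA"

    def test_unknown_chromosome_names_record(self):
        with pytest.raises(ValueError, match="e9"):
            annotate_genes(self.placements([("e9", "chrZ", 0, 10)]), self.GENES)

    def test_gene_bearing_fraction_recovered(self, genome, day0_circles_5000):
        _, truth = day0_circles_5000
        placements = c.simulate.truth_to_bed(truth)
        hits = annotate_genes(placements, genome.gene_models)
        frac = (hits["n_genes"] > 0).mean()
        p = 0.0352
        half_width = 1.96 * np.sqrt(p * (1 - p) / len(hits))
        assert abs(frac - p) <= half_width + 1e-9

    def test_gene_sets_grouped_by_condition(self):
        hits = pd.DataFrame(
            [{"ecc_id": "e1", "n_genes": 1, "genes": "gA"},
             {"ecc_id": "e2", "n_genes": 2, "genes": "gA,gB"},
             {"ecc_id": "e3", "n_genes": 0, "genes": ""}]
        )
        sets = gene_sets_by_condition(hits, {"e1": "D0", "e2": "C12", "e3": "C12"})
        assert sets == {"D0": {"gA"}, "C12": {"gA", "gB"}}


class TestConditionSummary:
    def test_single_sequence_gc_and_mean(self):
        rec = EccRecord("e1", "GC" * 25 + "AT" * 25, condition="D0")  # 100 bp, 50 GC
        summary = summarize_condition([rec])
        assert summary.gc_pct == 50.0
        assert summary.mean_length == 100
        assert summary.total_bases == 100

    def test_percentages_recomputable(self):
        s = ConditionSummary.from_totals(
            "C12", n_sequences=100, n_clustered=80, total_bases=400_000,
            masked_bases=150_000, gc_bases=164_000, n_gene_bearing=3,
            n_trna_bearing=7, n_trna_motifs=9, n_ori_bearing=2,
        )
        assert s.mean_length == 5000
        assert s.masked_pct == 37.5
        assert s.gc_pct == 41.0
        assert s.gene_pct == pytest.approx(3.75)
        assert s.trna_pct == pytest.approx(8.75)
        assert s.ori_pct == pytest.approx(2.5)

    def test_mixed_conditions_rejected(self):
        recs = [EccRecord("a", "ACGT", condition="D0"), EccRecord("b", "ACGT", condition="C12")]
        with pytest.raises(ValueError, match="condition"):
            summarize_condition(recs)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_condition([])
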