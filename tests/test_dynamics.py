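"""Gene presence partitions, fold changes and gain/loss concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import circulome as c
from circulome.dynamics import intersect_dynamics, log2fc, presence_matrix


def de_table(values: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame({"log2fc": pd.Series(values)})


class TestPresenceMatrix:
    def test_small_example_partition(self):
        p = presence_matrix({"A": {"g1", "g2"}, "B": {"g2"}, "C": set()})
        assert p.partition == {1: 1, 2: 1}
        assert p.unique_to("A") == {"g1"}

    def test_identical_sets_all_shared(self):
        sets = {"A": {"g1", "g2"}, "B": {"g1", "g2"}, "C": {"g1", "g2"}}
        p = presence_matrix(sets)
        assert p.partition == {3: 2}
        assert p.unique_to("A") == set()

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            presence_matrix({"A": {"g1"}})

    @given(st.lists(st.sets(st.integers(0, 30)), min_size=2, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_partition_sums_to_union(self, sets):
        gene_lists = {f"c{i}": {f"g{x}" for x in s} for i, s in enumerate(sets)}
        union = set().union(*gene_lists.values())
        if not union:
            with pytest.raises(ValueError):
                presence_matrix(gene_lists)
            return
        p = presence_matrix(gene_lists)
        assert sum(p.partition.values()) == len(union)
        # brute-force set algebra oracle
        for k, count in p.partition.items():
            brute = sum(
                1 for g in union
                if sum(g in s for s in gene_lists.values()) == k
            )
            assert brute == count


class TestLog2fc:
    def counts(self, means, nrep, rng, size=2000):
        return pd.DataFrame(
            {f"r{i}": rng.poisson(means) for i in range(nrep)},
            index=pd.Index([f"g{j}" for j in range(len(means))], name="gene_id"),
        )

    def test_equal_abundance_gives_zero(self):
        a = pd.DataFrame({"r1": [100, 200], "r2": [100, 200]}, index=["g1", "g2"])
        result = log2fc(a, a * 2)  # same composition, different depth
        assert result["log2fc"].abs().max() < 1e-12

    def test_fourfold_change_is_two(self):
        rng = np.random.default_rng(0)
        means = np.full(500, 2000.0)
        a = self.counts(means, 2, rng)
        b_means = means.copy()
        b_means[:10] *= 4
        b = self.counts(b_means, 2, rng)
        result = log2fc(a, b)
        assert result["log2fc"][:10].mean() == pytest.approx(2.0, abs=0.1)

    def test_swapping_groups_negates_exactly(self):
        rng = np.random.default_rng(1)
        a = self.counts(rng.uniform(10, 1000, 200), 3, rng)
        b = self.counts(rng.uniform(10, 1000, 200), 2, rng)
        fwd = log2fc(a, b)["log2fc"]
        rev = log2fc(b, a)["log2fc"]
        assert np.allclose(fwd, -rev)

    def test_zero_library_named(self):
        a = pd.DataFrame({"r1": [1, 2], "bad": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="bad"):
            log2fc(a, a)


class TestIntersectDynamics:
    PRESENCE = presence_matrix(
        {
            "D0": {"lost", "kept", "nodata"},
            "C12": {"gained_c", "kept", "weak"},
            "ST12": {"gained_s", "kept", "shared12"},
        }
    )

    def de(self):
        return {
            "C12": de_table({"lost": -2.5, "kept": 0.1, "gained_c": 2.4, "weak": 1.0,
                             "shared12": 0.2}),
            "ST12": de_table({"lost": -1.0, "kept": 0.0, "gained_s": 3.0, "shared12": 0.2}),
        }

    def test_rule_application(self):
        flagged = intersect_dynamics(self.PRESENCE, self.de()).set_index("gene_id")
        assert flagged.loc["lost", "flag"] == "loss-correlated"
        assert flagged.loc["gained_c", "flag"] == "gain-correlated"
        assert flagged.loc["gained_s", "flag"] == "gain-correlated"
        assert flagged.loc["weak", "flag"] == "neutral"
        assert flagged.loc["nodata", "flag"] == "no-expression-data"

    def test_day12_unique_uses_own_contrast_only(self):
        # gained_c rises only in C12; a hypothetical ST12 rise is irrelevant
        flagged = intersect_dynamics(self.PRESENCE, self.de()).set_index("gene_id")
        assert flagged.loc["gained_c", "uniqueness"] == "C12-unique"

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(60)]
        presence = presence_matrix(
            {"D0": set(genes[:30]), "C12": set(genes[25:45]), "ST12": set(genes[40:])}
        )
        de = {
            "C12": de_table({g: rng.normal(0, 2.5) for g in genes}),
            "ST12": de_table({g: rng.normal(0, 2.5) for g in genes}),
        }
        previous = None
        for bound in (1.0, 1.5, 2.0, 3.0):
            flagged = intersect_dynamics(presence, de, lo=-bound, hi=bound)
            n = (flagged["flag"].isin(["loss-correlated", "gain-correlated"])).sum()
            if previous is not None:
                assert n <= previous
            previous = n

    def test_planted_losses_and_gains_recovered_exactly(self, genome_many_genes):
        # low-dispersion regime: every planted effect is recoverable
        plan = c.default_de_plan(genome_many_genes, seed=3, n_loss=13, n_gain_c12=2,
                                 n_gain_st12=4, base_mean=2000, dispersion=0.01)
        counts, truth = c.simulate_rnaseq_counts(genome_many_genes, plan, seed=3)
        de_truth = truth.de_truth.set_index("gene_id")
        loss = set(de_truth.index[(de_truth["log2fc_C12"] < 0)])
        gain_c = set(de_truth.index[(de_truth["log2fc_C12"] > 0)])
        gain_s = set(de_truth.index[(de_truth["log2fc_ST12"] > 0)])
        steady = set(de_truth.index) - loss - gain_c - gain_s
        presence = presence_matrix(
            {"D0": loss | steady, "C12": gain_c | steady, "ST12": gain_s | steady}
        )
        cols = lambda p: [x for x in counts.columns if x.startswith(p)]
        de = {
            "C12": log2fc(counts[cols("D0_")], counts[cols("C12_")]),
            "ST12": log2fc(counts[cols("D0_")], counts[cols("ST12_")]),
        }
        flagged = intersect_dynamics(presence, de).set_index("gene_id")
        assert set(flagged.index[flagged["flag"] == "loss-correlated"]) == loss
        assert len(loss) == 13
        assert set(flagged.index[flagged["flag"] == "gain-correlated"]) == gain_c | gain_s
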