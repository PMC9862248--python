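"""Greedy identity clustering against a brute-force rotation oracle."""

import numpy as np
import pytest

from circulome._seq import revcomp, rotate, seq_to_array
from circulome.cluster import cluster_sequences, pairwise_identity, summarize_reduction
from conftest import mutate, random_circle


def brute_identity(a: str, b: str) -> float:
    """Oracle: exhaustive rotations x strands, exact position matching.

    Independent of the edit-distance implementation; restricted to
    equal-length circular sequences where rotation + Hamming is exact.
    """
    assert len(a) == len(b)
    arr_a = seq_to_array(a)
    best = 0.0
    for variant in (b, revcomp(b)):
        doubled = seq_to_array(variant + variant)
        for r in range(len(b)):
            ident = float(np.mean(arr_a == doubled[r : r + len(b)]))
            best = max(best, ident)
    return best


def brute_cluster(pairs, threshold):
    """Reference greedy clustering using the brute-force identity."""
    pairs = sorted(pairs, key=lambda t: (-len(t[1]), t[0]))
    seqs = dict(pairs)
    clusters = []
    for name, seq in pairs:
        for cl in clusters:
            if brute_identity(seq, seqs[cl[0]]) >= threshold:
                cl.append(name)
                break
        else:
            clusters.append([name])
    return {frozenset(cl) for cl in clusters}


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        s = random_circle(rng, 100)
        assert pairwise_identity(s, s) == 1.0

    def test_five_substitutions_in_100bp(self):
        rng = np.random.default_rng(1)
        s = random_circle(rng, 100)
        m = mutate(s, 5, rng)
        assert brute_identity(s, m) == pytest.approx(0.95)
        assert pairwise_identity(s, m) == pytest.approx(0.95, abs=0.01)

    def test_reverse_complement_is_identical(self):
        rng = np.random.default_rng(2)
        s = random_circle(rng, 100)
        assert pairwise_identity(s, revcomp(s)) == 1.0

    def test_rotation_is_identical(self):
        rng = np.random.default_rng(3)
        s = random_circle(rng, 120)
        assert pairwise_identity(s, rotate(s, 41)) == 1.0

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            s = random_circle(rng, 80)
            m = rotate(mutate(s, int(rng.integers(0, 10)), rng), int(rng.integers(80)))
            if rng.random() < 0.5:
                m = revcomp(m)
            assert pairwise_identity(s, m) >= brute_identity(s, m) - 1e-9
            assert pairwise_identity(s, m) == pytest.approx(brute_identity(s, m), abs=0.02)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


class TestClusterSequences:
    def test_dissimilar_sequences_stay_singletons(self):
        rng = np.random.default_rng(5)
        pairs = [(f"s{i}", random_circle(rng, 1000)) for i in range(5)]
        cset = cluster_sequences(pairs, threshold=0.90)
        assert cset.n_clusters == 5
        assert all(cl.size == 1 for cl in cset.clusters)

    def test_planted_clusters_recovered_exactly(self):
        rng = np.random.default_rng(6)
        pairs = []
        truth = []
        for i in range(10):
            base = random_circle(rng, 500)
            members = set()
            for j in range(3):
                copy = rotate(mutate(base, 10, rng), int(rng.integers(500)))  # 2% divergence
                name = f"c{i}_{j}"
                pairs.append((name, copy))
                members.add(name)
            truth.append(members)
        cset = cluster_sequences(pairs, threshold=0.90)
        found = {frozenset(m for m, _ in cl.members) for cl in cset.clusters}
        assert found == {frozenset(t) for t in truth}

    def test_exact_duplicate_joins_at_identity_one(self):
        rng = np.random.default_rng(7)
        s = random_circle(rng, 300)
        cset = cluster_sequences([("a", s), ("b", s)], threshold=0.90)
        assert cset.n_clusters == 1
        assert dict(cset.clusters[0].members)["b"] == 1.0

    def test_partition_property(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            local = np.random.default_rng(seed)
            pairs = [(f"s{i}", random_circle(local, int(local.integers(60, 200))))
                     for i in range(20)]
            cset = cluster_sequences(pairs, threshold=0.90)
            members = [m for cl in cset.clusters for m, _ in cl.members]
            assert sorted(members) == sorted(p[0] for p in pairs)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        pairs = []
        for i in range(8):
            base = random_circle(rng, 200)
            pairs.append((f"b{i}", base))
            pairs.append((f"m{i}", mutate(base, int(rng.integers(5, 60)), rng)))
        previous = None
        for threshold in (0.98, 0.9, 0.8, 0.6, 0.4):
            n = cluster_sequences(pairs, threshold=threshold).n_clusters
            if previous is not None:
                assert n <= previous
            previous = n

    def test_matches_bruteforce_reference(self):
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            pairs = []
            for i in range(10):
                base = random_circle(rng, 100)
                for j in range(3):
                    copy = rotate(mutate(base, 4, rng), int(rng.integers(100)))
                    pairs.append((f"c{i}_{j}", copy))
            for i in range(20):
                pairs.append((f"solo{i}", random_circle(rng, 100)))
            greedy = {
                frozenset(m for m, _ in cl.members)
                for cl in cluster_sequences(pairs, threshold=0.90).clusters
            }
            assert greedy == brute_cluster(pairs, 0.90)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            cluster_sequences([("a", "ACGT")], threshold=1.5)


class TestSummarizeReduction:
    def test_pooling_adds_counts(self):
        table = summarize_reduction({"X": 7, "Y": 5}, {"X": 3, "Y": 2})
        pooled = table.set_index("condition").loc["pooled"]
        assert pooled["sequences"] == 12 and pooled["clustered"] == 5

    def test_no_reduction(self):
        table = summarize_reduction({"X": 10}, {"X": 10})
        assert table.set_index("condition").loc["X", "reduction"] == 0

    def test_clustered_exceeding_raw_rejected(self):
        with pytest.raises(ValueError):
            summarize_reduction({"X": 5}, {"X": 6})
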