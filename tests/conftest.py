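import numpy as np
import pytest

import circulome as c


@pytest.fixture(scope="session")
def genome():
    """Small two-chromosome genome shared across tests."""
    return c.build_genome(c.GenomeConfig(), seed=7)


@pytest.fixture(scope="session")
def genome_many_genes():
    """Gene-rich genome for the differential-expression suites.

    Enough genes that planted DE genes are a small fraction of the
    transcriptome, as in real count data, so CPM library sizes are not
    dominated by the planted effects.
    """
    cfg = c.GenomeConfig(n_genes=400, gene_length=(1_000, 3_000))
    return c.build_genome(cfg, seed=11)


@pytest.fixture(scope="session")
def day0_circles_5000(genome):
    """A Day-0-profile circle population large enough for fraction checks."""
    circles, truth = c.sample_eccdna(genome, c.CONDITION_PROFILES["D0"], 5000, seed=1)
    return circles, truth.ecc_truth


def random_circle(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply exactly n substitutions at distinct positions."""
    arr = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        old = arr[pos]
        arr[pos] = "ACGT"[("ACGT".index(old) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)
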