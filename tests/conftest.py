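import numpy as np
import pytest

from admixkit.dataset import GenotypeDataset, make_marker_table


def build_dataset(genotypes, samples=None, chroms=None, positions=None,
                  ref="A", alt="G", ids=None):
    """Small-genotype test helper: rows = samples, columns = markers."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    samples = samples or [f"s{i + 1}" for i in range(n)]
    ids = ids or [f"snp{j + 1}" for j in range(m)]
    chroms = chroms or ["1"] * m
    positions = positions or list(range(100, 100 + 10 * m, 10))
    refs = [ref] * m if isinstance(ref, str) else ref
    alts = [alt] * m if isinstance(alt, str) else alt
    return GenotypeDataset(
        samples, make_marker_table(ids, chroms, positions, refs, alts), g
    )


@pytest.fixture
def tiny_dataset():
    """3 samples x 4 markers with one missing genotype."""
    return build_dataset(
        [[0, 1, 2, 0],
         [1, 1, 0, -1],
         [2, 0, 1, 2]]
    )


@pytest.fixture
def random_dataset():
    """40 samples x 300 markers of random dosages with sparse missingness."""
    rng = np.random.default_rng(42)
    p = rng.uniform(0.1, 0.9, 300)
    g = rng.binomial(2, p, (40, 300)).astype(np.int8)
    g[rng.random(g.shape) < 0.02] = -1
    return build_dataset(g, positions=list(range(1, 301)))


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Two long-diverged populations (10 diploids each), simulated once."""
    from admixkit.simulate import DemographicModel, SplitEvent, simulate

    model = DemographicModel(
        {"P1": 5_000.0, "P2": 5_000.0, "ANC": 10_000.0},
        splits=[SplitEvent(4000, "P1", "ANC"), SplitEvent(4000, "P2", "ANC")],
    )
    return simulate(model, samples={"P1": 20, "P2": 20}, n_loci=60,
                    locus_length=50_000, seed=202)
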