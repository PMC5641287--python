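import numpy as np
import pytest

import cdpop as cp
from cdpop import evaluation as ev


@pytest.fixture(scope="session")
def toy_k2():
    """Two unrelated phenotyped individuals: the hand-solvable CD instance."""
    return cp.KinshipMatrix(["a", "b"], np.eye(2))


@pytest.fixture(scope="session")
def genotype_pool():
    """A small simulated NAM genotype pool shared across tests."""
    gmap = cp.GeneticMap.uniform(n_chromosomes=2, loci_per_chromosome=40,
                                 length_cm=120.0)
    founders = cp.simulate_founders(5, gmap, seed=7)
    donors = founders.subset(individuals=founders.individual_ids[1:5])
    nam = cp.simulate_nam(founders.values[0], donors, [30, 30, 30, 30], gmap,
                          seed=8)
    return nam.genotypes


@pytest.fixture(scope="session")
def kinship_pool(genotype_pool):
    """Kinship over the pool, frequencies from the pool itself (centered K)."""
    freqs = cp.compute_allele_frequencies(genotype_pool)
    return cp.vanraden_kinship(genotype_pool, freqs)


@pytest.fixture(scope="session")
def draw_cd_instance(kinship_pool):
    """Factory for random (K, calibration set, contrast, lambda) instances."""

    def _draw(rng: np.random.Generator, n_max: int = 30):
        n = int(rng.integers(5, n_max + 1))
        ids = [
            kinship_pool.individual_ids[k]
            for k in rng.choice(kinship_pool.n, n, replace=False)
        ]
        K = kinship_pool.subset(ids)
        n_cal = int(rng.integers(1, n))
        cal = [ids[k] for k in rng.choice(n, n_cal, replace=False)]
        c = rng.normal(size=n)
        c -= c.mean()
        while np.abs(c).max() < 1e-6:  # pragma: no cover - essentially never
            c = rng.normal(size=n)
            c -= c.mean()
        lam = float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
        return K, cal, c, lam

    return _draw


@pytest.fixture(scope="session")
def small_dataset():
    """A compact NAM + panel dataset with phenotypes for scenario tests."""
    data, pop = ev.simulate_prediction_dataset(
        family_sizes=[25, 30, 35], n_panel=25, n_chromosomes=2,
        loci_per_chromosome=40, seed=42,
    )
    return data, pop
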