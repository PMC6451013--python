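import numpy as np
import pytest

from congenstatus.genodata import GenotypeDataset
from congenstatus.synthdata import study_regime, simulate


@pytest.fixture
def small_dataset() -> GenotypeDataset:
    """Two populations, three loci, six diploids — hand-checkable."""
    individuals = [f"i{k}" for k in range(1, 7)]
    populations = {i: ("A" if k < 3 else "B")
                   for k, i in enumerate(individuals)}
    calls = np.array([
        # L1        L2        L3
        [[100, 100], [150, 152], [200, 204]],
        [[100, 102], [150, 150], [200, 200]],
        [[102, 102], [152, 152], [204, 204]],
        [[104, 104], [150, 152], [200, 204]],
        [[104, 106], [152, 152], [204, 204]],
        [[106, 106], [150, 150], [0, 0]],
    ])
    return GenotypeDataset(individuals, populations, ["L1", "L2", "L3"], calls)


@pytest.fixture(scope="session")
def regime_dataset():
    """One draw from the study-regime simulator (shared across tests)."""
    ds, truth = simulate(study_regime(seed=11))
    return ds, truth


def random_dataset(rng: np.random.Generator, n_pops=2, n_per_pop=4,
                   n_loci=3, missing_frac=0.1) -> GenotypeDataset:
    """Random valid dataset for round-trip property tests."""
    individuals, populations, rows = [], {}, []
    for p in range(n_pops):
        for k in range(n_per_pop):
            ind = f"P{p}I{k}"
            individuals.append(ind)
            populations[ind] = f"P{p}"
    n = len(individuals)
    calls = rng.integers(90, 120, size=(n, n_loci, 2))
    miss = rng.random((n, n_loci)) < missing_frac
    calls[miss] = 0
    return GenotypeDataset(individuals, populations,
                           [f"L{j}" for j in range(n_loci)], calls)
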