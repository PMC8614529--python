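import numpy as np
import pytest

import ssgblup as sg


@pytest.fixture
def toy_pedigree():
    """Founders 1,2; 3 = (1,2); 4 = (1,3).  Hand-recursed tabular values:
    a34 = 0.75, a44 = 1.25, F4 = 0.25."""
    return sg.Pedigree(
        sire=np.array([0, 0, 1, 1]),
        dam=np.array([0, 0, 2, 3]),
        original_ids=np.array(["1", "2", "3", "4"], dtype=object),
    )


@pytest.fixture
def trio_pedigree():
    return sg.Pedigree(
        sire=np.array([0, 0, 1]),
        dam=np.array([0, 0, 2]),
        original_ids=np.array(["1", "2", "3"], dtype=object),
    )


def random_pedigree(rng: np.random.Generator, max_animals: int = 200) -> sg.Pedigree:
    """A random small pedigree via the simulator, varied in shape."""
    cfg = sg.SimulationConfig(
        n_founders=int(rng.integers(6, 60)),
        n_generations=int(rng.integers(1, 5)),
        offspring_per_dam=int(rng.integers(1, 3)),
        prop_sires=float(rng.uniform(0.1, 0.6)),
        prop_missing_parents=float(rng.uniform(0.0, 0.2)),
        n_snps=10,
        n_qtl=2,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ped = sg.simulate_pedigree(cfg)
    if ped.n_animals > max_animals:
        # truncating a topologically ordered pedigree keeps it valid
        keep = max_animals
        sire = ped.sire[:keep].copy()
        dam = ped.dam[:keep].copy()
        ped = sg.Pedigree(
            sire=sire, dam=dam, original_ids=ped.original_ids[:keep]
        )
    return ped


@pytest.fixture(scope="session")
def small_dataset():
    """Small but realistic simulated dataset shared across tests.

    ~500 animals over 3 generations, ~80 genotyped, 300 SNPs / 60 QTL,
    FD-like variance components.
    """
    cfg = sg.preset_config(
        "FD",
        n_founders=120,
        n_generations=3,
        n_snps=300,
        n_qtl=60,
        prop_genotyped=0.15,
        seed=42,
    )
    data, truth, full = sg.simulate_dataset(cfg)
    return cfg, data, truth, full
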