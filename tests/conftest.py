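import numpy as np
import pytest

import te_strain_scan as ts


@pytest.fixture(scope="session")
def small_family() -> ts.FamilyCopies:
    """One family: 5 near-identical active copies in strain A only, on a
    background of 6 shared degraded fragments."""
    spec = ts.TEFamilySpec(
        "POLY", consensus_length=1200, tir_length=60,
        n_active_copies_per_strain={"A": 5, "B": 0},
        active_divergence=0.01, n_degraded_copies=6,
        degraded_divergence_range=(0.10, 0.20),
        truncation_fraction_range=(0.3, 1.0), seed=11)
    return ts.simulate_family(spec)


@pytest.fixture(scope="session")
def small_genomes(small_family) -> dict[str, ts.SyntheticGenome]:
    return ts.build_genomes([small_family], background_length=80_000, seed=23)


@pytest.fixture(scope="session")
def small_index(small_family) -> ts.KmerIndex:
    lib = ts.RepeatLibrary({"POLY": small_family.consensus})
    return ts.build_index(lib, k=15)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140220)
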