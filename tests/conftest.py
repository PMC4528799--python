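import numpy as np
import pytest

from tlsdiffuse import (
    Ensemble,
    ToySpec,
    UnitCell,
    build_grid,
    generate_ensemble,
    make_two_group_benchmark,
)


@pytest.fixture(scope="session")
def bench():
    """Two-chain toy system with one physical TLS group per chain."""
    spec = ToySpec(n_atoms=40, seed=11)
    model, cell, groups = make_two_group_benchmark(spec)
    return model, cell, groups


@pytest.fixture(scope="session")
def small_ensemble(bench):
    """20-model independent ensemble of the benchmark system."""
    model, cell, groups = bench
    return generate_ensemble(model, cell, groups, n_models=20, seed=5)


@pytest.fixture(scope="session")
def small_map(small_ensemble):
    from tlsdiffuse import guinier_diffuse

    grid = build_grid(small_ensemble.cell, 4.0)
    return guinier_diffuse(small_ensemble, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
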