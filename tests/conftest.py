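import numpy as np
import pytest

from rapidgs import (
    SchemeConfig,
    assign_architecture,
    make_genetic_map,
    run_scheme,
    simulate_founders,
)

N_SCHEME_SEEDS = 10


@pytest.fixture(scope="session")
def small_map():
    return make_genetic_map(3, 50, 120.0, seed=11)


@pytest.fixture(scope="session")
def founders300(small_map):
    return simulate_founders(small_map, 300, seed=12, id_prefix="F")


@pytest.fixture(scope="session")
def arch_default(small_map, founders300):
    corr = np.array(
        [
            [1.0, 0.8, 0.4, 0.0],
            [0.8, 1.0, 0.4, 0.0],
            [0.4, 0.4, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return assign_architecture(
        small_map, founders300, 60, corr, np.array([5.0, 8.0, 15.0, 3.0]), seed=13
    )


@pytest.fixture(scope="session")
def scheme_runs():
    """Desk-scale scheme results across seeds (shared by several test files)."""
    cfg = SchemeConfig.scaled()
    return [run_scheme(cfg, seed) for seed in range(N_SCHEME_SEEDS)]


@pytest.fixture(scope="session")
def scheme_runs_truncation():
    """Same seeds under pure directional truncation on the early traits."""
    from dataclasses import replace

    cfg = replace(SchemeConfig.scaled(), criterion="truncation_early")
    return [run_scheme(cfg, seed) for seed in range(N_SCHEME_SEEDS)]
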