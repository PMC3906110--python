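import numpy as np
import pytest

from cystmir.simulate import SimulationConfig, make_reference, simulate_counts


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        seed=7,
        n_samples_per_group=4,
        n_mirna=12,
        n_clusters=5,
        mean_library_size=3000,
        dispersion=0.2,
        planted_log2fc={"miR-s05": 2.0},
        decoy_rpm={"decoy-hi": 300.0, "decoy-lo": 40.0},
    )


@pytest.fixture(scope="session")
def small_ref(small_cfg):
    return make_reference(small_cfg)


@pytest.fixture(scope="session")
def small_counts(small_cfg, small_ref):
    counts, samples, truth = simulate_counts(small_cfg, small_ref)
    return counts, samples, truth


@pytest.fixture(scope="session")
def two_group_design():
    """10 + 10 design: intercept and group indicator."""
    n = 20
    X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
    return X


def nb_counts(rng, q, lib_sizes, log2fc, dispersion, group):
    """Direct NB draw used as an independent data source in DE tests."""
    mean = lib_sizes[None, :] * q[:, None] * 2.0 ** (
        np.asarray(log2fc)[:, None] * np.asarray(group)[None, :]
    )
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, 1.0 / (1.0 + dispersion * mean))
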