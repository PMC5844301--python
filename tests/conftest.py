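import numpy as np
import pytest

from domsweep.simpop import (
    DemographyConfig,
    apply_sweep_introgression,
    simulate_haplotypes,
    simulate_reads,
)


def small_config(**kwargs) -> DemographyConfig:
    defaults = dict(n_per_subpop=4, L=100_000, seed=42)
    defaults.update(kwargs)
    if "sweep_interval" not in defaults:
        L = defaults["L"]
        defaults["sweep_interval"] = (int(0.4 * L), int(0.6 * L))
    return DemographyConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg() -> DemographyConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_haps(small_cfg):
    return simulate_haplotypes(small_cfg)


@pytest.fixture(scope="session")
def small_swept(small_cfg, small_haps):
    return apply_sweep_introgression(small_haps, small_cfg)


@pytest.fixture(scope="session")
def small_pile(small_cfg, small_swept):
    return simulate_reads(small_swept, mean_depth=2.0, e=0.001, seed=small_cfg.seed)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
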