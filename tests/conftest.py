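import numpy as np
import pytest

from finehap.simulate import (EffectSpec, PopulationSpec, SimConfig,
                              simulate_cohort)


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A reduced cohort that keeps every downstream stage exercised."""
    cfg = SimConfig(
        seed=seed,
        n_sites=200,
        population_specs=[
            PopulationSpec("EA", 60, switch_scale=500.0,
                           tag_hap_freqs={"hap1": 0.56, "hap2": 0.36,
                                          "hap5": 0.05, "hap6": 0.03}),
            PopulationSpec("AA", 400, switch_scale=2000.0,
                           tag_hap_freqs={"hap1": 0.31, "hap2": 0.28, "hap3": 0.175,
                                          "hap4": 0.145, "hap5": 0.03, "hap6": 0.02}),
        ],
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def zero_effects() -> EffectSpec:
    spec = EffectSpec(hap_log_or={}, eqtl_beta=0.0,
                      trait_beta=np.zeros(7), ordinal_beta=0.0)
    return spec


@pytest.fixture(scope="session")
def cohort():
    """One small cohort shared by read-only tests."""
    return simulate_cohort(small_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
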