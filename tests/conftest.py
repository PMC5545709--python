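import numpy as np
import pandas as pd
import pytest

from epivar.synth import StudyConfig, simulate_study


def small_config(**overrides) -> StudyConfig:
    """A fast small-scale study used across unit tests."""
    base = dict(
        n_probes=1200,
        n_cases=8,
        n_controls=10,
        n_panel=60,
        n_mesnv=6,
        n_mesnv_carrier_samples=4,
        dmr_n_probes=5,
        n_background_genes=6,
        n_detection_fail_probes=6,
        n_cross_reactive=6,
        n_snp_probes=6,
    )
    base.update(overrides)
    return StudyConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config(), seed=11)


@pytest.fixture()
def tight_controls():
    """Ten control betas around 0.9 with small spread."""
    rng = np.random.default_rng(5)
    return rng.normal(0.9, 0.02, size=10)
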