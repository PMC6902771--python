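import numpy as np
import pytest

from mirindex import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with three planted glioma markers."""
    cfg = simulate.SimulationConfig(
        n_mirnas=40,
        group_sizes={"diffuse_glioma": 30, "noncancer_1": 20, "noncancer_2": 20},
        marker_effects={"diffuse_glioma": [1.5, 1.2, -1.0]},
        seed=7,
    )
    return simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_three_tumor():
    """A small 3-class cohort with distinct per-class signatures."""
    cfg = simulate.three_tumor_config(
        seed=11,
        n_mirnas=50,
        group_sizes={"GBM": 30, "PCNSL": 20, "metastatic": 14},
        marker_effects={
            "GBM": [1.5, -1.5, 1.5, -1.5],
            "PCNSL": [1.5, -1.5, 1.5, -1.5],
            "metastatic": [1.5, -1.5, 1.5, -1.5],
        },
    )
    return simulate.generate_cohort(cfg)
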