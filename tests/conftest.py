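import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")

from dualscreen.descriptors import DescriptorMatrix
from dualscreen.templates import ScorerConfig, TargetTemplate, build_template


@pytest.fixture
def tiny_matrix() -> DescriptorMatrix:
    """Three compounds x five descriptors, no missing values."""
    values = pd.DataFrame(
        {
            "alpha": [1.0, 2.0, 3.0],
            "beta": [10.0, 10.5, 9.5],
            "gamma": [0.0, 0.0, 0.0],
            "delta": [-4.0, -5.0, -6.0],
            "epsilon": [100.0, 101.0, 99.0],
        },
        index=["c1", "c2", "c3"],
    )
    return DescriptorMatrix(values)


@pytest.fixture
def small_config() -> ScorerConfig:
    return ScorerConfig(n_descriptors=5, z_top=2)


@pytest.fixture
def tiny_template(tiny_matrix, small_config) -> TargetTemplate:
    return build_template(tiny_matrix, small_config, target_name="T1")


def make_template(means, sds, z_top, name="T") -> TargetTemplate:
    """Hand-built template with explicit moments for formula-level tests."""
    entries = pd.DataFrame(
        {
            "descriptor": [f"d{i}" for i in range(len(means))],
            "mean": np.asarray(means, dtype=float),
            "sd": np.asarray(sds, dtype=float),
        }
    )
    cfg = ScorerConfig(n_descriptors=len(means), z_top=z_top)
    return TargetTemplate(target_name=name, entries=entries, config=cfg)
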