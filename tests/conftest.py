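import numpy as np
import pandas as pd
import pytest

from nashsig.core import ExpressionMatrix, SampleDesign
from nashsig.simulate import SimulationConfig


@pytest.fixture
def tiny_counts() -> ExpressionMatrix:
    values = pd.DataFrame(
        [[2, 8], [8, 2], [5, 5]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(values=values, value_kind="counts")


@pytest.fixture
def two_group_design() -> SampleDesign:
    return SampleDesign(
        assignments={"a1": "ctrl", "a2": "ctrl", "b1": "case", "b2": "case"},
        group_order=("ctrl", "case"),
    )


@pytest.fixture
def small_config() -> SimulationConfig:
    # scaled-down study for fast unit tests
    return SimulationConfig(
        seed=7, n_genes=300, samples_per_group=4, human_samples_per_group=4,
        n_compounds=8, n_landmarks=200, cmap_arm_size=15,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
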