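import numpy as np
import pytest

from nanodot import DensityFunction, GradientSpec, generate_ordered, generate_random


@pytest.fixture(scope="session")
def linear_01_30():
    """Linear ramp 0.01 -> 0.30 over 100 µm (the canonical demo gradient)."""
    return DensityFunction("linear", 0.01, 0.30, 100.0)


@pytest.fixture(scope="session")
def ordered_linear_pattern(linear_01_30):
    return generate_ordered(GradientSpec(100.0, 100.0, linear_01_30, "ordered"))


@pytest.fixture(scope="session")
def random_exponential_pattern():
    density = DensityFunction("exponential", 0.01, 0.30, 100.0, k=3.0)
    return generate_random(GradientSpec(100.0, 100.0, density, "random", seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def constant_density(value: float, length: float) -> DensityFunction:
    return DensityFunction("linear", value, value, length)
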