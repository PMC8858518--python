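import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expression(rng):
    """12 samples x 6 genes, all distinct values, no planted structure."""
    values = rng.standard_normal((12, 6))
    return pd.DataFrame(
        values,
        index=[f"S{i}" for i in range(12)],
        columns=[f"G{j}" for j in range(6)],
    )


@pytest.fixture
def fixture_pair():
    """The bundled 50-gene walk-through dataset with one planted pair per type."""
    from csdnet.simulate import default_fixture_spec, generate

    return generate(default_fixture_spec(seed=0))
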