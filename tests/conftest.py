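import numpy as np
import pytest

from fgict import FilterParams, run_table5_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def table5_report():
    """The phantom benchmark rows needed by the acceptance checks, computed
    once per session at the default 256x256x64 study conditions."""
    return run_table5_experiment(
        size=(256, 256, 64),
        seed=1234,
        params=FilterParams(),
        rows=["gaussian_var0.0005", "gaussian_var0.005", "impulsive"],
    )
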