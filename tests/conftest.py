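import numpy as np
import pytest

from perisim.geometry import assign_sectors, build_grid
from perisim.observer_sim import Observer, ResponseParams, TrueField


@pytest.fixture(scope="session")
def grid30():
    return build_grid("30-2")


@pytest.fixture(scope="session")
def grid66():
    return build_grid("SPARK66")


@pytest.fixture(scope="session")
def sector_map(grid66):
    return assign_sectors(grid66)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def deterministic_params():
    """Effectively noiseless responder: steep psychometric slope, no lapses."""
    return ResponseParams(
        fp_rate=0.0, fn_rate=0.0, sigma_min=1e-9, sigma_max=1e-9
    )


@pytest.fixture
def make_uniform_observer(deterministic_params):
    """Observer with a flat true field at a chosen sensitivity."""

    def _make(grid, sensitivity, params=None, age=50.0):
        fld = TrueField(grid, np.full(len(grid), float(sensitivity)))
        return Observer(
            uid="uniform",
            group="normal",
            age=age,
            true_field=fld,
            params=params or deterministic_params,
        )

    return _make
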