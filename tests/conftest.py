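import numpy as np
import pytest

from flocscatter import (AggregateModel, QGrid, ScatteringCurve,
                         composite_intensity, fractal_intensity)

GRID_STEP_FACTOR = 10 ** (5 / 199)  # one step of the default 200-pt grid


@pytest.fixture
def default_grid() -> QGrid:
    return QGrid.logspace(1e-3, 1e2, 200)


@pytest.fixture
def power_law_curve(default_grid) -> ScatteringCurve:
    """Exact I = q^-2.2 over the whole default grid."""
    return ScatteringCurve(default_grid,
                           fractal_intensity(default_grid.q, 2.2))


@pytest.fixture
def composite_model() -> AggregateModel:
    """Crossovers at q1 = 1/20 and q2 = 1/0.5 per um."""
    return AggregateModel(rg_um=60.0, rp_um=0.5, a_um=20.0, df=2.2)


@pytest.fixture
def composite_curve(composite_model, default_grid) -> ScatteringCurve:
    return composite_intensity(composite_model, default_grid)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
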