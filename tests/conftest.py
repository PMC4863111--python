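import numpy as np
import pytest

from glucolag import (
    CapillaryParams,
    GlucoseTimeSeries,
    GTTProfileParams,
    ModelConfig,
    StarlingParams,
    TissueParams,
)


@pytest.fixture
def capillary_k1() -> CapillaryParams:
    """Exchange ratio k = P*A/F = 1."""
    return CapillaryParams(permeability=25.0, area=0.12, flow=3.0)


@pytest.fixture
def starling_symmetric() -> StarlingParams:
    """Crossover at the axial midpoint: equal filtration/absorption areas."""
    return StarlingParams(k_f=1.0, sigma_pi_c=25.0, p_a=35.0, p_v=15.0)


@pytest.fixture
def tissue_default() -> TissueParams:
    return TissueParams(d_um2_per_min=600.0, x_um=24.0, c_isf0=100.0)


@pytest.fixture
def gtt_blood() -> GlucoseTimeSeries:
    """Dense noiseless GTT blood profile (1-min sampling, 120 min)."""
    t = np.arange(0.0, 120.0 + 1e-9, 1.0)
    return GlucoseTimeSeries(t, GTTProfileParams().evaluate(t), label="blood")


@pytest.fixture
def default_config() -> ModelConfig:
    return ModelConfig()


def constant_series(value: float, n: int = 7, dt: float = 10.0) -> GlucoseTimeSeries:
    return GlucoseTimeSeries(dt * np.arange(n), np.full(n, value))
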