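import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petkin import (
    AMMONIA_FRAMING,
    WATER_FRAMING,
    InputFunction,
    ParentFractionFit,
    SampledCurve,
    build_parent_plasma_input,
    make_schedule,
)
from petkin.synthetic import SyntheticConfig, arterial_truth

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ammonia_schedule():
    return make_schedule(AMMONIA_FRAMING)


@pytest.fixture(scope="session")
def water_schedule():
    return make_schedule(WATER_FRAMING)


@pytest.fixture(scope="session")
def bolus_curve_30min() -> SampledCurve:
    """Deterministic arterial whole-blood curve on a 1 s grid over 30 min."""
    cfg = SyntheticConfig()
    dt = 1.0 / 60.0
    t = np.arange(0.0, 30.0 + dt / 2, dt)
    return SampledCurve(t, arterial_truth(cfg, t))


@pytest.fixture(scope="session")
def bolus_curve_5min() -> SampledCurve:
    cfg = SyntheticConfig()
    dt = 1.0 / 60.0
    t = np.arange(0.0, 5.0 + dt / 2, dt)
    return SampledCurve(t, arterial_truth(cfg, t))


@pytest.fixture(scope="session")
def ammonia_input(bolus_curve_30min) -> InputFunction:
    """Metabolite-corrected input with the default parent-fraction truth."""
    pf = ParentFractionFit(A=0.65, alpha=0.5, beta=0.04)
    return build_parent_plasma_input(bolus_curve_30min, pob=1.14, pf=pf, delay_s=0.0)


@pytest.fixture(scope="session")
def water_input(bolus_curve_5min) -> InputFunction:
    return InputFunction(whole_blood=bolus_curve_5min,
                         parent_plasma=bolus_curve_5min, pob=1.0)
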