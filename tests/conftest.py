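import pytest
from hypothesis import HealthCheck, settings

import thermleaf as tl

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wt():
    return tl.wt_parameters()


@pytest.fixture(scope="session")
def env25():
    return tl.default_environment(25.0)


@pytest.fixture(scope="session")
def calibrated():
    """Calibrated leaf configuration: ci_ratio 0.7, day respiration omitted."""
    return tl.calibrated_parameters(), tl.calibrated_environment()


@pytest.fixture(scope="session")
def calibrated_curves(calibrated):
    """Default 10–45°C sweeps for WT and the strategy stacks, calibrated."""
    params, env = calibrated
    stacks = ([], ["RA"], ["PR"], ["RUBP"], ["RA", "PR"],
              ["RA", "RUBP"], ["PR", "RUBP"], ["RA", "PR", "RUBP"])
    curves = {}
    for names in stacks:
        ps = tl.combine(names, params)
        curves[ps.label] = tl.temperature_sweep(ps, env)
    return curves
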