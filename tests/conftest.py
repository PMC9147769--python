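import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vbdm import ModelParameters, Trajectory

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_params() -> ModelParameters:
    """The fixed single-run setting used throughout the worked examples:
    DOM 30, B 1e5, V 1e6, T -2 C, g 0.09, mu 0.024, gamma 1, phi 1e-10."""
    return ModelParameters(
        N_i=30.0, B_i=1e5, V_i=1e6, T=-2.0, g_exudate=0.09,
        mu=0.024, gamma=1.0, phi=1e-10, beta=250.0,
    )


@pytest.fixture()
def synthetic_trajectory(worked_params) -> Trajectory:
    """Hand-built trajectory (not integrated): constant DOM, oscillating
    populations well above the viability floor."""
    t = np.arange(0.0, 50_000.0 + 1, 50.0)
    b = 1e5 * (1.0 + 0.5 * np.sin(2 * np.pi * t / 700.0))
    v = 1e6 * (1.0 + 0.5 * np.cos(2 * np.pi * t / 700.0))
    n = np.full_like(t, 30.0)
    return Trajectory(t=t, N=n, B=b, V=v, params=worked_params)
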