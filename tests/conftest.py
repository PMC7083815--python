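"""Shared fixtures: reference systems and reusable simulation runs."""

import numpy as np
import pytest

import crnoise as cn
from crnoise.noise import NoiseModel

try:  # deterministic property testing when hypothesis is present
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def preset():
    return cn.schnakenberg_preset()


@pytest.fixture(scope="session")
def schnakenberg_J(preset):
    return preset.jacobian()


@pytest.fixture(scope="session")
def white_model():
    return NoiseModel(covariance=np.ones((2, 2)), variant="white")


# Turing-unstable Schnakenberg variant: homogeneous state stable
# (trace J < 0, det J > 0) but mode m = 1 grows under diffusion.
TURING_UNSTABLE = {
    "params": {"k1": 9.0, "k2": 11.0, "k3": 0.005, "k-1": 2.0},
    "diffusion": np.array([1e-4, 0.02]),
}


@pytest.fixture(scope="session")
def white_reference_run(preset, white_model):
    """White-noise study run reused across spectral tests: reference grid,
    20 repetitions, horizon 200, recording step 0.01 (shared because it
    costs about two minutes)."""
    A = cn.assemble_A(preset.jacobian(), preset.diffusion, preset.grid)
    trajs = cn.simulate_linear(
        A, white_model, preset.grid, T=200.0, dt=0.01, seed=0, reps=20
    )
    emp = cn.periodogram(trajs)
    ana = cn.analytic_spectrum(
        preset.jacobian(),
        preset.diffusion,
        preset.grid,
        lambda w: cn.noise_spectrum_N(white_model, w),
        emp.omegas,
    )
    return {"empirical": emp, "analytic": ana}
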