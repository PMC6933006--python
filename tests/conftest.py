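import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session", autouse=True)
def _quiet_warnings():
    import warnings
    warnings.filterwarnings("ignore", category=FutureWarning)
    warnings.filterwarnings("ignore", category=UserWarning)
    warnings.filterwarnings("ignore", category=RuntimeWarning)


def make_circle_stroke(radius_cm: float = 10.0, period_s: float = 5.0,
                       rate_hz: float = 200.0, speed_factor: float = 1.0):
    """Constant-speed planar circle as a Stroke (analytic curvature 1/r)."""
    from moveson.kinematics import Stroke

    t = np.arange(0.0, period_s / speed_factor, 1.0 / rate_hz)
    w = 2 * np.pi * speed_factor / period_s
    xyz = np.column_stack([radius_cm * np.cos(w * t),
                           radius_cm * np.sin(w * t),
                           np.zeros_like(t)])
    return Stroke(t=t, xyz=xyz, direction="up", rate_hz=rate_hz)


@pytest.fixture(scope="session")
def circle_stroke():
    return make_circle_stroke()


@pytest.fixture(scope="session")
def coupled_trials():
    """Strongly coupled, preprocessed and epoched recording (shared)."""
    from moveson.neurophys import epoch, preprocess
    from moveson.simulate import CouplingDesign, gen_ephys

    design = CouplingDesign(coupling_strength=0.9, n_trials=60,
                            coupled_channels=("C3", "F3", "P3"), seed=11)
    rec = preprocess(gen_ephys(design))
    return epoch(rec, reject_ptp_uv=None)


@pytest.fixture(scope="session")
def null_trials():
    """Uncoupled recording, 100 trials (shared null fixture)."""
    from moveson.neurophys import epoch, preprocess
    from moveson.simulate import CouplingDesign, gen_ephys

    design = CouplingDesign(coupling_strength=0.0, n_trials=100, seed=0)
    rec = preprocess(gen_ephys(design))
    return epoch(rec, reject_ptp_uv=None)
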