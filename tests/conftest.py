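import numpy as np
import pytest

from frapkit import KineticsTruth, RawTrace, SimulationSpec


@pytest.fixture
def default_kinetics() -> KineticsTruth:
    return KineticsTruth(y0=0.1, a1=0.48, t1=2.0, a2=0.32, t2=12.0)


@pytest.fixture
def clean_spec(default_kinetics) -> SimulationSpec:
    """Corruption-free simulation: no noise, no acquisition bleaching."""
    return SimulationSpec(
        kinetics=default_kinetics,
        noise_sd=0.0,
        cell_cv=0.0,
        acq_bleach_rate=0.0,
        seed=0,
    )


def make_trace(
    cell_id="c1",
    f_roi=None,
    f_total=None,
    f_bg=None,
    n_prebleach=5,
    n_frames=20,
    dt=0.25,
) -> RawTrace:
    """Hand-assembled trace with simple defaults for unit tests."""
    t = np.arange(n_frames) * dt
    if f_roi is None:
        f_roi = np.full(n_frames, 100.0)
        f_roi[n_prebleach:] = 50.0
    if f_total is None:
        f_total = np.full(n_frames, 100.0)
    if f_bg is None:
        f_bg = np.zeros(n_frames)
    return RawTrace(
        cell_id=cell_id,
        time_s=t,
        f_roi=np.asarray(f_roi, float),
        f_total=np.asarray(f_total, float),
        f_bg=np.asarray(f_bg, float),
        n_prebleach=n_prebleach,
    )
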