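import numpy as np
import pytest

from performotor import synthetic_data as sd
from performotor.signal_model import UNIT_IDS, SensorRecording, unit_axes


@pytest.fixture(scope="session")
def tremor_recording():
    """One default short-protocol session with tremor episodes (240 s, 64 Hz)."""
    cfg = sd.default_config("TREMOR", seed=7)
    rec, annotations, diaries = sd.simulate_recording(cfg)
    return rec, annotations, diaries


@pytest.fixture(scope="session")
def small_tremor_cohort():
    """Four patients x 1 session, short sessions — fast end-to-end material."""
    cfg = sd.default_config("TREMOR", duration_s=180.0)
    return sd.simulate_cohort(4, 1, cfg, seed=11)


def make_recording(n_samples=640, fs=64.0, seed=0, patient="P00", session="S00"):
    """Random-but-valid recording for plumbing tests (no symptom structure)."""
    rng = np.random.default_rng(seed)
    data = {
        u: 0.05 * rng.standard_normal((n_samples, len(unit_axes(u))))
        for u in UNIT_IDS
    }
    for u in UNIT_IDS:
        data[u][:, 2] += 1.0  # gravity along z
    return SensorRecording(
        patient_id=patient, session_id=session, fs=fs, data=data
    ).validate()


@pytest.fixture
def random_recording():
    return make_recording()
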