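import numpy as np
import pytest

from cvtscreen.io import NightRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_recording(
    raw_lvs,
    rr=None,
    quality=None,
    subject_id="S000",
    recording_index=1,
    session_end=None,
):
    """Build a small valid recording from explicit per-beat columns."""
    raw_lvs = np.asarray(raw_lvs, dtype=float)
    n = len(raw_lvs)
    rr = np.full(n, 1000.0) if rr is None else np.asarray(rr, dtype=float)
    quality = np.full(n, 15, dtype=int) if quality is None else np.asarray(quality, dtype=int)
    t = np.cumsum(rr) / 1000.0
    end = session_end if session_end is not None else float(t[-1]) + 1.0
    return NightRecording(
        subject_id=subject_id,
        recording_index=recording_index,
        session_start=0.0,
        session_end=end,
        t=t,
        rr=rr,
        raw_lvs=raw_lvs,
        quality=quality,
    )


@pytest.fixture
def recording_factory():
    return make_recording
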