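import numpy as np
import pandas as pd
import pytest

from fmpmaze import MazeGeometry, SessionConfig, TurnSequence


@pytest.fixture
def cfg():
    return SessionConfig()


@pytest.fixture
def geometry():
    return MazeGeometry()


@pytest.fixture
def events_frame():
    """Minimal 3-row single-subject arm-entry log."""
    return pd.DataFrame(
        {
            "time_s": [1.0, 5.0, 9.0],
            "subject_id": ["f0", "f0", "f0"],
            "zone": ["arm0", "arm1", "arm2"],
        }
    )


def make_seq(tokens, times=None, subject_id="f0"):
    tokens = np.array(list(tokens), dtype="<U1")
    if times is None:
        times = np.arange(1.0, len(tokens) + 1.0)
    return TurnSequence(
        subject_id=subject_id, tokens=tokens, turn_times_s=np.asarray(times, float)
    )


@pytest.fixture
def seq_factory():
    return make_seq
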