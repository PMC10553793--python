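import numpy as np
import pytest

from msitr.data import (
    PreferenceWeight,
    StatePath,
    TrialDataset,
    TrialRecord,
)

W_RESPONSE = PreferenceWeight((0.0, 1.0, 0.0))
W_PFS = PreferenceWeight((1.0, 1.0, 0.0))


def make_record(entries, tilde_t, delta, a=1, z=(0.0,), sid=None):
    return TrialRecord(
        z=np.asarray(z, dtype=float),
        a=a,
        path=StatePath(tuple(entries), float(tilde_t), int(delta)),
        subject_id=sid,
    )


@pytest.fixture
def w_response():
    return W_RESPONSE


@pytest.fixture
def w_pfs():
    return W_PFS


@pytest.fixture
def three_subject_dataset():
    """(tilde_t, delta) = (1,1), (2,0), (3,1): one censoring at t=2."""
    recs = [
        make_record([(0.0, 1), (1.0, 3)], 1.0, 1, a=1, sid="s1"),
        make_record([(0.0, 1)], 2.0, 0, a=-1, sid="s2"),
        make_record([(0.0, 1), (3.0, 3)], 3.0, 1, a=1, sid="s3"),
    ]
    return TrialDataset(recs, tau=3.0, n_states=3)


@pytest.fixture
def response_path():
    """1 on [0,1), 2 on [1,2.5), absorbed (state 3) at 2.5; fully observed."""
    return StatePath(((0.0, 1), (1.0, 2), (2.5, 3)), 2.5, 1)
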