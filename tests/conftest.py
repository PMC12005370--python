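import numpy as np
import pytest

from srtpipe.core_io import Session, Trial, TrialEvents
from srtpipe import synth_tasks as st


@pytest.fixture
def toy_session() -> Session:
    """Three hand-written SRT trials: correct, premature, late."""
    trials = [
        Trial(index=0, press_time=10.0, fp=1.0, stim_time=11.0,
              release_time=11.25, poke_time=12.5, cue_kind="stimulus"),
        Trial(index=1, press_time=20.0, fp=1.0, release_time=20.8,
              cue_kind="stimulus"),
        Trial(index=2, press_time=30.0, fp=0.5, stim_time=30.5,
              release_time=31.4, cue_kind="stimulus"),
    ]
    return Session(rat_id="r1", session_index=0, phase="Pre", post_ordinal=0,
                   lesion_group="none", task="srt", trials=trials)


@pytest.fixture
def jittered_events() -> list[TrialEvents]:
    """Twenty trials with reaction-time and poke-latency jitter."""
    rng = np.random.default_rng(11)
    out = []
    for i in range(20):
        press = 10.0 * (i + 1)
        stim = press + 1.5
        release = stim + 0.2 + 0.2 * rng.random()
        poke = release + 1.0 + 0.5 * rng.random()
        out.append(TrialEvents(trial_index=i, press=press, stim=stim,
                               release=round(release, 3), poke=round(poke, 3)))
    return out


@pytest.fixture
def default_srt_params() -> st.DeadlineModelParams:
    return st.DeadlineModelParams()
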