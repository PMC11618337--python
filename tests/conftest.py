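import numpy as np
import pytest

from reachkin.synthetic_data import single_reach_trial
from reachkin.trajectory_io import Group


def build_reach_trial(
    amplitude=0.3,
    duration=1.0,
    reaction_time=0.3,
    fs=100.0,
    direction=(1.0, 0.0, 0.0),
    time_to_peak_fraction=0.5,
    pre_go_s=0.5,
    tail_s=0.0,
    group=Group.TD,
    noise_sd=0.0,
    seed=0,
    subject_id="S01",
    trial_index=1,
):
    """Single-reach fixture; returns (trial, true_onset_sample)."""
    return single_reach_trial(
        amplitude_m=amplitude,
        duration_s=duration,
        reaction_time_s=reaction_time,
        sampling_rate_hz=fs,
        direction=direction,
        time_to_peak_fraction=time_to_peak_fraction,
        pre_go_s=pre_go_s,
        tail_s=tail_s,
        group=group,
        noise_sd_m=noise_sd,
        seed=seed,
        subject_id=subject_id,
        trial_index=trial_index,
    )


@pytest.fixture
def min_jerk_trial():
    """Canonical noiseless fixture: A=0.3 m, T=1 s, 100 Hz, 0.3 s delay."""
    return build_reach_trial()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
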