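import numpy as np
import pytest

from vmdcm import dcm_core as dcm
from vmdcm import synthetic_data as gen


@pytest.fixture(scope="session")
def schedules_one():
    """One default session (6 x 21 s blocks, 15 s rests)."""
    return gen.generate_task_schedule(1, seed=0)


@pytest.fixture(scope="session")
def two_block_schedule():
    """A short two-block session (one per condition) for fast EMG tests."""
    return gen.TaskSchedule(
        session_index=0,
        blocks=[("TTNF", 5.0, 21.0), ("TT", 41.0, 21.0)],
        rest_s=15.0, lead_in_s=5.0)


@pytest.fixture(scope="session")
def group_mean_params():
    return gen.make_ground_truth(n_subjects=3, seed=0).group_mean


@pytest.fixture(scope="session")
def noiseless_fit(schedules_one, group_mean_params):
    """Noise-free BOLD at the group-mean connectivity, inverted once."""
    data = gen.simulate_subject_bold(group_mean_params, schedules_one,
                                     obs_noise_sd=0.0, seed=0)
    post = dcm.invert_subject(data, staged=False, max_iter=24)
    return group_mean_params, data, post


@pytest.fixture(scope="session")
def emg_cohort(schedules_one):
    """Two subjects' preprocessed, segmented repetition features."""
    import pandas as pd
    from vmdcm import emg as emg_mod
    frames = []
    for i in range(2):
        rec = gen.generate_subject_emg(schedules_one, mdf_ratio=1.02,
                                       amp_ratio=1.07, seed=11,
                                       subject_index=i)[0]
        tgt = gen.generate_target_trace(schedules_one[0], seed=11 + 7919 * i)
        clean = emg_mod.preprocess_emg(rec)
        bounds = emg_mod.segment_repetitions(clean, tgt)
        frames.append(emg_mod.repetition_features(clean, bounds, subject=i))
    return pd.concat(frames, ignore_index=True)
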