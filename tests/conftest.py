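import numpy as np
import pandas as pd
import pytest

import sstlab as sl
from sstlab.cohort import sessions_to_frames


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but full-pipeline cohort (12 participants, all variants)."""
    cc = sl.CohortConfig(n_per_variant=4, seed=7, miss_day_prob=0.2)
    return sl.generate_cohort(cc)


@pytest.fixture(scope="session")
def one_participant_frames():
    """Trial/session frames for a single 4-session race-model participant."""
    prof = sl.ParticipantProfile(
        participant_id="P1", variant="points", stop_mean=260.0, dropout_hazard=1.0
    )
    recs = sl.simulate_participant(prof, sl.CohortConfig(n_per_variant=1), sl.TaskConfig(), 99)
    return sessions_to_frames(recs)


def make_session_trials(
    rng,
    n_go=180,
    go_rt_loc=500.0,
    go_rt_scale=60.0,
    failed_stop_loc=410.0,
    ssd_levels=(100.0, 150.0, 200.0, 250.0, 300.0),
    n_per_ssd=12,
    respond_probs=(0.15, 0.3, 0.5, 0.7, 0.85),
    rt_ssd_slope=0.3,
):
    """Hand-built session trial log with controllable race-model signatures."""
    rows = []
    i = 0
    for _ in range(n_go):
        i += 1
        rows.append(
            dict(
                participant_id="X",
                session_number=1,
                block=1,
                trial_index=i,
                trial_type="go",
                ssd_ms=None,
                staircase_id=None,
                outcome="go_success",
                rt_ms=float(rng.normal(go_rt_loc, go_rt_scale)),
                points=0.0,
                bonus_after=1,
            )
        )
    for ssd, p in zip(ssd_levels, respond_probs):
        for _ in range(n_per_ssd):
            i += 1
            responded = rng.random() < p
            rt = float(rng.normal(failed_stop_loc + rt_ssd_slope * ssd, 40.0)) if responded else None
            rows.append(
                dict(
                    participant_id="X",
                    session_number=1,
                    block=1,
                    trial_index=i,
                    trial_type="stop",
                    ssd_ms=ssd,
                    staircase_id=1,
                    outcome="stop_respond" if responded else "stop_inhibit",
                    rt_ms=rt,
                    points=0.0,
                    bonus_after=1,
                )
            )
    return pd.DataFrame(rows)
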