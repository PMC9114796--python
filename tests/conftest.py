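"""Shared fixtures.

The expensive fixtures (rendered cohorts) are session-scoped and reused by
several test modules; everything is generated programmatically at test
time from fixed seeds.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pytest

from gaitpath.cli_pipeline import PipelineConfig, stage_estimate, stage_features
from gaitpath.synthetic_gait import (
    GROUPS,
    CohortSpec,
    SensorNoise,
    make_default_profiles,
    simulate_cohort,
    simulate_session,
)

FS = 100.0


@pytest.fixture(scope="session")
def profiles():
    return make_default_profiles()


@pytest.fixture(scope="session")
def quiet_session(profiles):
    """One noise-free 20-stride straight-walk session with stored truth."""
    spec = CohortSpec(strides_per_session=20, n_turns=0)
    return simulate_session(
        profiles["healthy_older"], spec, seed=1, noise=SensorNoise.silent()
    )


@pytest.fixture(scope="session")
def noisy_session(profiles):
    """Default-noise 70-stride session with two turns."""
    spec = CohortSpec(strides_per_session=70, n_turns=2)
    return simulate_session(profiles["mild_pd"], spec, seed=2)


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """Rendered 10-per-group cohort run through estimation and features.

    Returns (sessions, truth_table, feature_table).
    """
    spec = CohortSpec(counts={g: 10 for g in GROUPS}, strides_per_session=70,
                      n_turns=2, seed=0)
    sessions, truth_table = simulate_cohort(spec=spec)
    config = PipelineConfig()
    out = tmp_path_factory.mktemp("cohort")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        estimates, _ = stage_estimate(config, Path(out), sessions)
        table, _, _ = stage_features(config, Path(out), sessions, estimates)
    return sessions, truth_table, table


@pytest.fixture(scope="session")
def feature_table(default_cohort):
    return default_cohort[2]


def match_strides(session, truth, estimates, side, max_dt=0.05):
    """Pair estimated strides with truth records by heel-strike time."""
    series = getattr(session, side)
    hs_true = truth.heel_strikes(side)
    out = []
    for seg, traj in zip(estimates[side]["segments"], estimates[side]["trajectories"]):
        t0 = series.time[seg.heel_strike_index]
        k = int(np.argmin(np.abs(hs_true[:-1] - t0)))
        if abs(hs_true[k] - t0) < max_dt:
            out.append((truth.strides[side][k], seg, traj))
    return out
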