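import numpy as np
import pytest

from gaitpath.gait_features import (
    EventConfig,
    FeatureError,
    GaitEvents,
    LiftNotDetectedError,
    SpatialFeatures,
    StrideFlags,
    detect_max_clearance,
    detect_support_change,
    detect_toe_off,
    extract_features,
    participant_features,
    select_strides,
    session_stride_features,
)
from gaitpath.trajectory_estimation import StrideTrajectory, estimate_trajectories
from tests.conftest import match_strides

FS = 100.0


def make_trajectory(forward, vertical, fs=FS):
    n = len(forward)
    t = np.arange(n) / fs
    pos = np.column_stack([forward, np.zeros(n), vertical])
    vel = np.gradient(pos, t, axis=0)
    return StrideTrajectory(time=t, position=pos, velocity=vel)


class TestDetectToeOff:
    def test_analytic_stride_within_30ms(self, quiet_session):
        session, truth = quiet_session
        res = estimate_trajectories(session)
        for side in ("left", "right"):
            for rec, _seg, traj in match_strides(session, truth, res, side):
                to = detect_toe_off(traj)
                true_rel = rec.toe_off_t - rec.start_t
                assert abs(to - true_rel) < 0.030

    def test_flat_trajectory_flagged_failed(self):
        traj = make_trajectory(np.linspace(0, 1, 100), np.zeros(100))
        with pytest.raises(LiftNotDetectedError):
            detect_toe_off(traj)

    def test_invariant_to_forward_offset(self):
        n = 120
        z = np.r_[np.zeros(40), 0.05 * np.sin(np.pi * np.arange(40) / 40.0) + 0.0,
                  np.zeros(40)]
        z[40:80] = 0.12 * np.sin(np.pi * np.arange(40) / 40.0)
        x = np.linspace(0, 1.0, n)
        a = detect_toe_off(make_trajectory(x, z))
        b = detect_toe_off(make_trajectory(x + 5.0, z))
        assert a == b


class TestDetectMaxClearance:
    def test_constructed_peak(self):
        n = 101
        z = np.sin(np.pi * np.arange(n) / (n - 1)) * 0.15  # peak at centre
        t_mc = detect_max_clearance(make_trajectory(np.linspace(0, 1, n), z))
        assert t_mc == pytest.approx(0.5 * (n - 1) / FS, abs=1.01 / FS)

    def test_plateau_breaks_to_earliest(self):
        z = np.zeros(100)
        z[50:53] = 0.2  # 3-sample plateau
        t_mc = detect_max_clearance(make_trajectory(np.linspace(0, 1, 100), z))
        assert t_mc == pytest.approx(50 / FS)

    def test_v2_equals_vertical_max(self):
        rng = np.random.default_rng(0)
        z = np.abs(np.convolve(rng.normal(0, 1, 100), np.ones(10) / 10, "same"))
        traj = make_trajectory(np.linspace(0, 1, 100), z)
        t_mc = detect_max_clearance(traj)
        events = GaitEvents(0.0, 0.01, max(t_mc, 0.02), traj.time[-1], traj.time[-1])
        feats = extract_features(traj, events, mid_stance_t=0.0,
                                 config=EventConfig(vertical_reference="onset"))
        assert feats.V2 == pytest.approx(z.max() - z[0], abs=1e-9)


class TestDetectSupportChange:
    def test_contralateral_convention_clamps_into_window(self):
        t, used = detect_support_change(
            terminal_hs_t=10.0, stride_start_t=9.0, stride_duration=1.0,
            contralateral_toe_offs=[9.6, 10.12],
        )
        assert used == "contralateral_toe_off_after_terminal_hs"
        assert t == pytest.approx(1.0)  # 10.12 clamped to the stride end

    def test_contralateral_event_inside_window(self):
        t, _ = detect_support_change(
            terminal_hs_t=9.9, stride_start_t=9.0, stride_duration=1.0,
            contralateral_toe_offs=[9.95],
        )
        assert t == pytest.approx(0.95)

    def test_missing_contralateral_falls_back(self):
        t, used = detect_support_change(
            terminal_hs_t=10.0, stride_start_t=9.0, stride_duration=1.0,
            contralateral_toe_offs=None,
        )
        assert used == "terminal_heel_strike"
        assert t == pytest.approx(1.0)

    def test_truth_agreement_and_ordering(self, quiet_session):
        session, truth = quiet_session
        res = estimate_trajectories(session)
        recs = session_stride_features(
            res, {"left": session.left.time, "right": session.right.time}
        )
        for side in ("left", "right"):
            for r in recs[side]:
                if r.events is None:
                    continue
                assert r.events.support_change_t >= r.events.max_clearance_t
                # truth instant under the same convention
                match = [
                    s for s in truth.strides[side]
                    if abs(s.start_t - r.start_t) < 0.05
                ]
                if match:
                    true_rel = match[0].support_change_t - match[0].start_t
                    assert abs(r.events.support_change_t - true_rel) < 0.030


class TestExtractFeatures:
    def test_all_zero_trajectory(self):
        traj = make_trajectory(np.zeros(100), np.zeros(100))
        events = GaitEvents(0.0, 0.2, 0.5, 0.9, 0.99)
        feats = extract_features(traj, events, mid_stance_t=0.1)
        assert all(v == 0 for v in feats.as_dict().values())

    def test_clearance_dominates(self, quiet_session):
        session, truth = quiet_session
        res = estimate_trajectories(session)
        recs = session_stride_features(
            res, {"left": session.left.time, "right": session.right.time}
        )
        for side in ("left", "right"):
            for r in recs[side]:
                if r.features is None:
                    continue
                assert r.features.V2 >= r.features.V1 - 1e-9
                assert r.features.V2 >= r.features.V3 - 1e-9
                assert r.features.F1 <= r.features.F2 <= r.features.F3 + 1e-9

    def test_event_outside_stride_raises(self):
        traj = make_trajectory(np.linspace(0, 1, 50), np.zeros(50))
        # support change beyond the trajectory window
        bad = GaitEvents(0.0, 0.1, 0.2, 2.0, 5.0)
        with pytest.raises(ValueError):
            GaitEvents(0.0, 0.3, 0.2, 0.4, 0.49)  # toe-off after clearance
        with pytest.raises((FeatureError, ValueError)):
            extract_features(traj, bad, mid_stance_t=0.1)

    def test_estimated_features_match_truth(self, quiet_session):
        session, truth = quiet_session
        res = estimate_trajectories(session)
        recs = session_stride_features(
            res, {"left": session.left.time, "right": session.right.time}
        )
        checked = 0
        for side in ("left", "right"):
            truth_by_t = sorted(truth.strides[side], key=lambda r: r.start_t)
            starts = np.array([r.start_t for r in truth_by_t])
            for r in recs[side]:
                if r.features is None or r.flags.initial or r.flags.final:
                    continue
                k = int(np.argmin(np.abs(starts - r.start_t)))
                tr = truth_by_t[k]
                if abs(tr.start_t - r.start_t) > 0.05 or tr.features is None:
                    continue
                checked += 1
                assert r.features.F3 == pytest.approx(tr.features["F3"], abs=0.02)
                assert r.features.V2 == pytest.approx(tr.features["V2"], abs=0.01)
                assert r.features.V3 == pytest.approx(tr.features["V3"], abs=0.01)
        assert checked >= 15


class TestSelectStrides:
    @staticmethod
    def flags(n, turns=(), failed=()):
        return [
            StrideFlags(turn=i in turns, failed=i in failed, initial=i < 5,
                        final=i >= n - 5)
            for i in range(n)
        ]

    def test_protocol_yields_40_total(self):
        per_leg = []
        for _ in range(2):
            sel = select_strides(self.flags(35, turns=(15, 16)), quota=20)
            per_leg.append(sel.n_selected)
        assert per_leg == [20, 20]
        assert sum(per_leg) == 40

    def test_shortfall_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="shortfall"):
            sel = select_strides(self.flags(12), quota=20)
        assert sel.n_selected == 2
        assert sel.shortfall

    def test_turn_strides_never_selected(self):
        sel = select_strides(self.flags(40, turns=(12, 20)), quota=30)
        assert not sel.selected[12]
        assert not sel.selected[20]

    def test_idempotent_and_flag_driven(self):
        f = self.flags(35, turns=(10,))
        a = select_strides(f, quota=20)
        b = select_strides(f, quota=20)
        assert a.selected == b.selected

    def test_failed_strides_excluded(self):
        sel = select_strides(self.flags(35, failed=(7, 8)), quota=30)
        assert not sel.selected[7]
        assert not sel.selected[8]


class TestParticipantFeatures:
    def test_identical_strides_mean_equals_value(self):
        f = SpatialFeatures(0.2, 0.9, 1.2, 0.05, 0.15, 0.08)
        flags = [StrideFlags(initial=False, final=False)] * 3
        sel = select_strides(flags, quota=3, n_edge=0)
        row = participant_features([f, f, f], sel, "p1", "mild_pd")
        assert row["F3"] == pytest.approx(1.2)
        assert row["n_strides"] == 3

    def test_mean_arithmetic(self):
        a = SpatialFeatures(0, 0, 1.0, 0, 0, 0)
        b = SpatialFeatures(0, 0, 1.2, 0, 0, 0)
        sel = select_strides([StrideFlags(), StrideFlags()], quota=2, n_edge=0)
        row = participant_features([a, b], sel, "p1", "mild_pd")
        assert row["F3"] == pytest.approx(1.1)

    def test_zero_selected_returns_none(self):
        sel = select_strides([StrideFlags(turn=True)], quota=2, n_edge=0)
        assert participant_features(
            [SpatialFeatures(0, 0, 0, 0, 0, 0)], sel, "p1", "mild_pd"
        ) is None

    def test_cohort_participant_means_near_truth(self, default_cohort):
        _, truth_table, table = default_cohort
        merged = table.merge(truth_table, on="participant_id", suffixes=("", "_true"))
        for feat in ("F3", "V2"):
            err = (merged[feat] - merged[f"{feat}_true"]).abs()
            assert err.median() < 0.01


class TestGroupOrderings:
    def test_all_significant_contrasts_hold_on_estimates(self, default_cohort):
        _, _, table = default_cohort
        gm = table.groupby("group")[["F1", "F2", "F3", "V1", "V2", "V3"]].mean()
        y, o, m, a = "healthy_young", "healthy_older", "mild_pd", "advanced_pd"
        # forward
        for f in ("F2", "F3"):
            assert gm.loc[y, f] > gm.loc[o, f] > gm.loc[m, f] > gm.loc[a, f]
        assert gm.loc[m, "F1"] < gm.loc[y, "F1"]
        for g in (m, o, y):
            assert gm.loc[a, "F1"] < gm.loc[g, "F1"]
        # vertical: mild largest, advanced smallest
        for v in ("V1", "V2", "V3"):
            assert gm.loc[m, v] > gm.loc[y, v] > gm.loc[o, v] > gm.loc[a, v]
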