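"""In-stride gait events, the six spatial features, and stride selection.

The six features are the forward (F1-F3) and vertical (V1-V3) displacements
of the estimated ankle trajectory at three in-stride events: toe-off (1),
maximum clearance (2) and change of supporting leg (3).  Forward
displacements are measured from the stride-onset heel strike.  Vertical
displacements are, by default, measured from the mid-stance (foot-flat)
level of the stride rather than from the heel-strike sample: the estimator
pins the vertical channel to zero at both stride boundaries, so a
heel-strike-referenced vertical displacement at the stride end would be
identically zero and carry no information.  The reference is configurable
(``vertical_reference="onset"`` restores the literal heel-strike reference)
and is recorded in the conventions metadata.

Event-detection conventions (none of the three instants has a canonical
operational definition) are config enums; every output records which
conventions produced it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory_estimation import StrideTrajectory

logger = logging.getLogger(__name__)

FEATURES = ("F1", "F2", "F3", "V1", "V2", "V3")


class FeatureError(ValueError):
    pass


class LiftNotDetectedError(FeatureError):
    """No sustained foot lift found: stride flagged failed."""


@dataclass(frozen=True)
class EventConfig:
    #: toe-off detector: "vertical_velocity" (default) or "gyro_trough"
    toe_off_method: str = "vertical_velocity"
    #: support-change convention: "contralateral_toe_off_after_terminal_hs"
    #: (default) or "terminal_heel_strike"
    support_change: str = "contralateral_toe_off_after_terminal_hs"
    #: vertical displacement reference: "midstance" (default) or "onset"
    vertical_reference: str = "midstance"
    #: minimum peak height (m) for a stride to count as lifted
    min_lift: float = 0.005

    def as_metadata(self) -> dict[str, str]:
        return {k: str(v) for k, v in asdict(self).items()}


@dataclass
class GaitEvents:
    """Event instants in seconds from the stride-onset heel strike."""

    heel_strike_t: float
    toe_off_t: float
    max_clearance_t: float
    support_change_t: float
    stride_duration: float
    support_change_convention: str = "contralateral_toe_off_after_terminal_hs"

    def __post_init__(self):
        if not (self.heel_strike_t <= self.toe_off_t < self.max_clearance_t):
            raise ValueError("need heel_strike <= toe_off < max_clearance")
        if not (0.0 <= self.support_change_t <= self.stride_duration + 1e-9):
            raise ValueError("support_change_t outside the stride window")


@dataclass
class SpatialFeatures:
    F1: float
    F2: float
    F3: float
    V1: float
    V2: float
    V3: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FEATURES}


@dataclass
class StrideFlags:
    turn: bool = False
    initial: bool = False
    final: bool = False
    failed: bool = False


@dataclass
class StrideSelection:
    """Outcome of the exclusion protocol for one leg."""

    selected: list[bool]
    flags: list[StrideFlags]
    quota: int
    shortfall: bool = False

    @property
    def n_selected(self) -> int:
        return int(sum(self.selected))


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def _interp(t: np.ndarray, y: np.ndarray, at: float) -> float:
    return float(np.interp(at, t, y))


def detect_max_clearance(trajectory: StrideTrajectory, after_t: float = 0.0) -> float:
    """Time of the vertical maximum over the (post-toe-off) swing interval.

    Plateau ties break to the earliest sample.
    """
    t = trajectory.time
    z = trajectory.position[:, 2]
    m = t >= after_t
    i = int(np.argmax(z[m]))  # argmax returns the first maximum
    return float(t[m][i])


def detect_toe_off(
    trajectory: StrideTrajectory,
    config: EventConfig | None = None,
    gyro_sagittal: np.ndarray | None = None,
) -> float:
    """Onset of sustained foot lift before the clearance peak.

    Default method: the last local minimum of vertical velocity that is
    still followed by an above-threshold swing ascent — the lull between
    the heel-off rise and the ascent.  Uses the vertical channel only.
    Raises :class:`LiftNotDetectedError` when the trajectory never lifts
    above ``min_lift``.
    """
    config = config or EventConfig()
    t = trajectory.time
    z = trajectory.position[:, 2]
    z_rel = z - z.min()
    if float(z_rel.max()) < config.min_lift:
        raise LiftNotDetectedError(
            f"no foot lift above {config.min_lift * 1e3:.0f} mm in this stride"
        )
    i_peak = int(np.argmax(z))
    if config.toe_off_method == "gyro_trough":
        if gyro_sagittal is None:
            raise ValueError("gyro_trough method needs the gyro stride slice")
        g = np.asarray(gyro_sagittal, dtype=float)
        k = min(i_peak, len(g) - 1)
        j = int(np.argmin(g[:k])) if k > 0 else 0
        return float(t[j])

    vz = np.gradient(z, t)
    if len(vz) >= 3:  # light smoothing against sample noise
        vz = np.convolve(vz, np.ones(3) / 3.0, mode="same")
    vmax = float(np.max(vz[: max(i_peak, 1)])) if i_peak > 0 else 0.0
    if vmax <= 0:
        raise LiftNotDetectedError("vertical velocity never positive before the peak")
    thresh = 0.3 * vmax
    # toe-off = the last local minimum of vertical velocity that is still
    # followed by a sustained (above-threshold) swing ascent before the
    # clearance peak; minima inside the pre-peak deceleration are thereby
    # excluded without any altitude heuristic
    run_max = np.maximum.accumulate(vz[:i_peak][::-1])[::-1]  # max of vz[i:i_peak]
    best = None
    for i in range(1, i_peak - 1):
        if (
            vz[i] <= vz[i - 1]
            and vz[i] <= vz[i + 1]
            and vz[i] < thresh
            and run_max[i] > thresh
        ):
            best = i
    if best is not None:
        return float(t[best])
    # monotone ascent (no heel-off lull): onset of sustained lift
    strong = np.flatnonzero(vz[:i_peak] > thresh)
    if len(strong) == 0:
        return float(t[0])
    weak = np.flatnonzero(vz[: strong[0]] <= 0.05 * vmax)
    return float(t[weak[-1]]) if len(weak) else float(t[0])


def detect_support_change(
    terminal_hs_t: float,
    stride_start_t: float,
    stride_duration: float,
    contralateral_toe_offs: Sequence[float] | None = None,
    config: EventConfig | None = None,
) -> tuple[float, str]:
    """Support-change instant (stride-relative) and the convention used.

    Default convention: the contralateral toe-off immediately following
    this stride's terminal heel strike, clamped into the stride window.
    Falls back to the terminal heel strike when no contralateral event
    qualifies.  All times absolute (session clock) except the returned
    stride-relative instant.
    """
    config = config or EventConfig()
    convention = config.support_change
    if convention == "contralateral_toe_off_after_terminal_hs":
        if contralateral_toe_offs is not None and len(contralateral_toe_offs):
            cto = np.asarray(contralateral_toe_offs, dtype=float)
            after = cto[cto > terminal_hs_t + 1e-9]
            if len(after):
                t_abs = min(float(after[0]), stride_start_t + stride_duration)
                return t_abs - stride_start_t, convention
        logger.debug("no qualifying contralateral toe-off; falling back")
        convention = "terminal_heel_strike"
    if convention == "terminal_heel_strike":
        return stride_duration, convention
    raise ValueError(f"unknown support-change convention {config.support_change!r}")


def extract_features(
    trajectory: StrideTrajectory,
    events: GaitEvents,
    mid_stance_t: float | None = None,
    config: EventConfig | None = None,
) -> SpatialFeatures:
    """Read the six displacements off the trajectory at the event instants.

    Linear interpolation between samples.  Forward displacements are
    relative to the stride onset; vertical displacements relative to the
    configured reference level (mid-stance by default).
    """
    config = config or EventConfig()
    t = trajectory.time
    for name, at in (
        ("toe_off_t", events.toe_off_t),
        ("max_clearance_t", events.max_clearance_t),
        ("support_change_t", events.support_change_t),
    ):
        if not (t[0] - 1e-9 <= at <= t[-1] + 1e-9):
            raise FeatureError(f"{name}={at:.3f}s outside the stride window")
    x = trajectory.position[:, 0]
    z = trajectory.position[:, 2]
    x0 = _interp(t, x, events.heel_strike_t)
    if config.vertical_reference == "midstance":
        if mid_stance_t is None:
            raise ValueError("midstance vertical reference needs mid_stance_t")
        z0 = _interp(t, z, mid_stance_t)
    elif config.vertical_reference == "onset":
        z0 = _interp(t, z, events.heel_strike_t)
    else:
        raise ValueError(f"unknown vertical_reference {config.vertical_reference!r}")
    f = lambda at: _interp(t, x, at) - x0
    v = lambda at: _interp(t, z, at) - z0
    return SpatialFeatures(
        F1=f(events.toe_off_t),
        F2=f(events.max_clearance_t),
        F3=f(events.support_change_t),
        V1=v(events.toe_off_t),
        V2=v(events.max_clearance_t),
        V3=v(events.support_change_t),
    )


# ---------------------------------------------------------------------------
# Stride selection (protocol exclusions) and aggregation
# ---------------------------------------------------------------------------

def select_strides(
    flags: Sequence[StrideFlags],
    quota: int = 20,
    n_edge: int = 5,
) -> StrideSelection:
    """Apply the exclusion protocol to one leg's time-ordered strides.

    Drops the first and last ``n_edge`` strides, every turn-flagged and
    every failed stride, then keeps the first ``quota`` survivors.  If
    fewer than ``quota`` remain they are all kept and a shortfall warning
    is emitted (never padded).
    """
    flags = list(flags)
    n = len(flags)
    selected = [False] * n
    kept = 0
    for i, fl in enumerate(flags):
        if i < n_edge or i >= n - n_edge:
            continue
        if fl.turn or fl.failed or fl.initial or fl.final:
            continue
        if kept < quota:
            selected[i] = True
            kept += 1
    shortfall = kept < quota
    if shortfall:
        warnings.warn(
            f"stride selection shortfall: {kept} of {quota} strides available",
            stacklevel=2,
        )
    return StrideSelection(selected=selected, flags=flags, quota=quota, shortfall=shortfall)


def participant_features(
    stride_features: Sequence[SpatialFeatures],
    selection: StrideSelection | Sequence[StrideSelection],
    participant_id: str,
    group: str,
    aggregate: str = "mean",
) -> dict | None:
    """Aggregate selected strides to one FeatureTable row.

    ``stride_features`` must be the concatenation (in order) of the strides
    covered by the selection(s).  Returns ``None`` (with a log entry) when
    nothing was selected.
    """
    selections = [selection] if isinstance(selection, StrideSelection) else list(selection)
    mask = [s for sel in selections for s in sel.selected]
    if len(mask) != len(stride_features):
        raise ValueError("selection and stride_features lengths differ")
    chosen = [f for f, keep in zip(stride_features, mask) if keep]
    if not chosen:
        logger.warning("participant %s: zero selected strides, excluded", participant_id)
        return None
    agg = np.mean if aggregate == "mean" else np.median
    row = {"participant_id": participant_id, "group": group}
    for k in FEATURES:
        row[k] = float(agg([getattr(f, k) for f in chosen]))
    row["n_strides"] = len(chosen)
    return row


# ---------------------------------------------------------------------------
# Session-level driver
# ---------------------------------------------------------------------------

@dataclass
class StrideFeatureRecord:
    side: str
    start_t: float
    duration: float
    events: GaitEvents | None
    features: SpatialFeatures | None
    flags: StrideFlags


def session_stride_features(
    estimates: dict[str, dict],
    session_time: dict[str, np.ndarray],
    config: EventConfig | None = None,
    turn_windows: Sequence[tuple[float, float]] = (),
) -> dict[str, list[StrideFeatureRecord]]:
    """Detect events and extract features for every estimated stride.

    ``estimates`` is the output of
    :func:`gaitpath.trajectory_estimation.estimate_trajectories`;
    ``session_time`` maps side -> the session time vector (for absolute
    stride times).  Strides whose onset falls inside any ``turn_windows``
    interval are flagged as turns.  Dropped strides reappear here as
    failed-flagged records so that the selection protocol sees the full
    time-ordered stride list.
    """
    config = config or EventConfig()

    # first pass: toe-off instants per side (needed contralaterally)
    toe_offs_abs: dict[str, list[float]] = {"left": [], "right": []}
    per_side_raw: dict[str, list] = {}
    for side, res in estimates.items():
        t_vec = session_time[side]
        rows = []
        for seg, traj in zip(res["segments"], res["trajectories"]):
            start_t = float(t_vec[seg.start_index])
            try:
                to_t = detect_toe_off(traj, config)
            except LiftNotDetectedError:
                rows.append((seg, traj, start_t, None, None))
                continue
            mc_t = detect_max_clearance(traj, after_t=to_t)
            ms_t = float(t_vec[seg.mid_stance_index]) - start_t
            rows.append((seg, traj, start_t, to_t, (mc_t, ms_t)))
            toe_offs_abs[side].append(start_t + to_t)
        per_side_raw[side] = rows

    out: dict[str, list[StrideFeatureRecord]] = {}
    for side, rows in per_side_raw.items():
        other = "right" if side == "left" else "left"
        records: list[StrideFeatureRecord] = []
        for seg, traj, start_t, to_t, rest in rows:
            duration = traj.duration
            in_turn = any(a <= start_t < b for a, b in turn_windows)
            if to_t is None:
                records.append(
                    StrideFeatureRecord(
                        side, start_t, duration, None, None,
                        StrideFlags(turn=in_turn, failed=True),
                    )
                )
                continue
            mc_t, ms_t = rest
            sc_t, used = detect_support_change(
                terminal_hs_t=start_t + duration,
                stride_start_t=start_t,
                stride_duration=duration,
                contralateral_toe_offs=toe_offs_abs.get(other),
                config=config,
            )
            try:
                events = GaitEvents(
                    heel_strike_t=0.0,
                    toe_off_t=to_t,
                    max_clearance_t=mc_t,
                    support_change_t=sc_t,
                    stride_duration=duration,
                    support_change_convention=used,
                )
                feats = extract_features(traj, events, mid_stance_t=ms_t, config=config)
            except (FeatureError, ValueError) as e:
                logger.info("%s stride @%.2fs failed feature stage: %s", side, start_t, e)
                records.append(
                    StrideFeatureRecord(
                        side, start_t, duration, None, None,
                        StrideFlags(turn=in_turn, failed=True),
                    )
                )
                continue
            records.append(
                StrideFeatureRecord(side, start_t, duration, events, feats,
                                    StrideFlags(turn=in_turn))
            )
        # dropped strides from the estimator become failed records
        for d in estimates[side]["dropped"]:
            t_vec = session_time[side]
            start_t = float(t_vec[min(d.start_index, len(t_vec) - 1)])
            in_turn = any(a <= start_t < b for a, b in turn_windows)
            records.append(
                StrideFeatureRecord(side, start_t, 0.0, None, None,
                                    StrideFlags(turn=in_turn, failed=True))
            )
        records.sort(key=lambda r: r.start_t)
        # mark protocol edge strides
        for i, r in enumerate(records):
            r.flags.initial = i < 5
            r.flags.final = i >= len(records) - 5
        out[side] = records
    return out


def build_feature_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble participant rows into the canonical FeatureTable."""
    cols = ["participant_id", "group", *FEATURES, "n_strides"]
    df = pd.DataFrame(list(rows), columns=cols)
    if df[list(FEATURES)].isna().any().any():
        raise FeatureError("FeatureTable contains missing feature values")
    return df
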