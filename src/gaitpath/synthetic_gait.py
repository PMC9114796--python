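"""Ground-truthed synthetic gait sessions rendered into shank-IMU signals.

The generator builds world-frame ankle-point kinematics for each leg from a
piecewise-polynomial stride model and then renders them into sensor-frame
accelerometer/gyroscope series, so that every downstream stage (event
detection, strapdown trajectory estimation, feature extraction, statistics,
classification) can be exercised against stored analytic truth.

Stride model (closed forms)
---------------------------
One stride spans ``[0, T]`` between consecutive heel strikes of the same
foot.  With ``s`` the stance fraction and ``c`` the clearance phase, the
internal anchors are::

    t_drop = 0.12 T                    post-heel-strike descent to foot-flat
    t_ms   = 0.5 s T                   mid-stance (quasi-static anchor)
    t_rest = T - ~0.05 T               terminal rest onset (see below)
    t_ho   = sT - 0.4 (t_rest - sT)    heel-off; onset of forward progression

* forward path progress: flat until ``t_ho``, a slow quintic pre-swing
  advance covering 12% of the stride length by toe-off, a short dwell, and
  the main swing smoothstep reaching ``stride_length`` at ``t_rest``; the
  terminal rest plateau keeps the ankle exactly at rest through the heel
  strike so the estimator's zero-endpoint-velocity assumption holds in a
  neighbourhood of every stride boundary;
* vertical: smoothstep ``z_start -> 0`` (by ``t_drop``), flat 0, a rise to
  ``toe_off_height`` with a dwell around ``sT``, then curvature-matched
  quintics peaking sharply at ``max_clearance`` at ``cT`` and settling to
  ``terminal_height`` at ``t_rest``;
* shank pitch: a small cubic about mid-stance during stance (pitch rate
  exactly zero at ``t_ms``, growing quadratically away from it) and a
  quintic Hermite + degree-6 bump during swing, matched in value, rate and
  angular acceleration at the joins.

All channels are C^2 across segment and stride boundaries, so acceleration
is the exact analytic second derivative of position (vertical and, on
straight bouts, forward).  Horizontal world *position* is obtained by
trapezoidal quadrature of the analytic velocity on the sample grid; because
the velocity is C^2 with zero end derivatives the quadrature error is
negligible (far below sensor noise).

Turns are rendered as short low-amplitude strides during which the heading
rotates by pi (smoothstep); they are flagged in ground truth and excluded
by the selection protocol, so no attempt is made to model realistic turning
dynamics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import PPoly
from scipy.spatial.transform import Rotation

from .imu_io import GRAVITY, ImuSeries, SensorSpec, WalkSession, session_to_csv

GROUPS = ("mild_pd", "advanced_pd", "healthy_older", "healthy_young")

# Fixed alignment of the sensor axes onto the world axes at zero pitch/yaw:
# sensor x -> world x (forward), sensor y -> world z (up),
# sensor z -> world -y (lateral), right handed.
R0 = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])

_STANCE_ROTATION = 0.10  # rad of forward shank rotation over stance
_F1_FRACTION = 0.12  # fraction of stride length covered before toe-off
_SWING_BUMP = 0.55  # rad, amplitude of the swing pitch excursion
_RAMP = 0.4  # s, stand <-> walk pitch blending ramp


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrideParams:
    """Ground-truth spatial/temporal parameters of a single stride."""

    stride_length: float  # m
    max_clearance: float  # m, peak ankle height above foot-flat
    toe_off_height: float  # m, ankle height at toe-off
    terminal_height: float  # m, ankle height at the terminal heel strike
    stride_duration: float  # s
    stance_fraction: float = 0.62  # in (0, 1)
    clearance_phase: float = 0.80  # in (stance_fraction, 1)

    def __post_init__(self):
        for name in ("stride_length", "max_clearance", "toe_off_height", "terminal_height"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.stride_duration <= 0:
            raise ValueError("stride_duration must be > 0")
        if not (0.0 < self.stance_fraction < self.clearance_phase < 1.0):
            raise ValueError("need 0 < stance_fraction < clearance_phase < 1")
        if self.max_clearance < max(self.toe_off_height, self.terminal_height) - 1e-12:
            raise ValueError("max_clearance must dominate toe-off and terminal heights")

    def phases(self) -> dict[str, float]:
        """Internal time anchors (seconds from stride onset)."""
        T = self.stride_duration
        t_ms = 0.5 * self.stance_fraction * T
        t_drop = min(0.12 * T, 0.8 * t_ms)
        t_to = self.stance_fraction * T
        t_mc = self.clearance_phase * T
        t_rest = T - min(max(0.035 * T, 0.025), 0.05)
        t_rest = max(t_rest, t_mc + 0.25 * (T - t_mc))
        # heel-off precedes toe-off by a fixed fraction of the swing time,
        # so the pre-toe-off forward progress scales with stride length
        t_ho = t_to - 0.4 * (t_rest - t_to)
        if t_ho <= t_ms:
            t_ho = 0.5 * (t_ms + t_to)
        # brief dwell around toe-off: the ankle pauses between the heel-off
        # rise and the swing ascent, which anchors toe-off detection even
        # when the heel-off rise is small
        dwell = min(0.03, 0.4 * (t_mc - t_to), 0.4 * (t_to - t_ho))
        t_to_start = t_to - 0.5 * dwell
        t_to_end = t_to + 0.5 * dwell
        return {
            "t_drop": t_drop,
            "t_ms": t_ms,
            "t_ho": t_ho,
            "t_to": t_to,
            "t_to_start": t_to_start,
            "t_to_end": t_to_end,
            "t_mc": t_mc,
            "t_rest": t_rest,
            "t_end": T,
        }


@dataclass(frozen=True)
class StrideSpread:
    """StrideParams-shaped standard deviations (all >= 0)."""

    stride_length: float = 0.0
    max_clearance: float = 0.0
    toe_off_height: float = 0.0
    terminal_height: float = 0.0
    stride_duration: float = 0.0
    stance_fraction: float = 0.0
    clearance_phase: float = 0.0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} sd must be >= 0")


@dataclass(frozen=True)
class GroupProfile:
    group: str
    mean: StrideParams
    between_subject_sd: StrideSpread = field(default_factory=StrideSpread)
    within_subject_sd: StrideSpread = field(default_factory=StrideSpread)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")


@dataclass(frozen=True)
class SensorNoise:
    """Additive sensor artefacts for :func:`render_imu`."""

    accel_noise_sd: float = 0.25  # m/s^2, white
    gyro_noise_sd: float = 0.02  # rad/s, white
    accel_bias: tuple[float, float, float] = (0.02, -0.015, 0.01)  # m/s^2
    gyro_bias: tuple[float, float, float] = (0.002, -0.001, 0.0015)  # rad/s
    hs_spike_amplitude: float = 12.0  # rad/s, added on the sensor sagittal channel
    hs_spike_width: float = 0.12  # s, full width of the raised-cosine transient

    def __post_init__(self):
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if self.hs_spike_width <= 0:
            raise ValueError("hs_spike_width must be > 0")

    @classmethod
    def silent(cls) -> "SensorNoise":
        """Noise-free render (heel-strike spikes retained)."""
        return cls(0.0, 0.0, (0.0, 0.0, 0.0), (0.0, 0.0, 0.0))


@dataclass(frozen=True)
class CohortSpec:
    counts: dict[str, int] = field(
        default_factory=lambda: {g: 8 for g in GROUPS}
    )
    strides_per_session: int = 70
    n_turns: int = 2
    turn_indices: tuple[int, ...] | None = None  # 0-based stride indices
    seed: int = 0
    sampling_rate: float = 100.0

    def __post_init__(self):
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("participant counts must be >= 0")
        if self.strides_per_session < 1:
            raise ValueError("strides_per_session must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")

    def resolved_turn_indices(self) -> tuple[int, ...]:
        if self.turn_indices is not None:
            return tuple(sorted(self.turn_indices))
        n, k = self.strides_per_session, self.n_turns
        return tuple((j + 1) * n // (k + 1) for j in range(k))


def make_default_profiles() -> dict[str, GroupProfile]:
    """Default group profiles.

    The means realize the qualitative group orderings this artifact targets:
    forward extent (stride length) healthy_young > healthy_older > mild_pd >
    advanced_pd, and vertical amplitudes mild_pd > healthy_young >
    healthy_older > advanced_pd.  Between-subject spreads are deliberately
    wide relative to the group gaps (as in real cohorts), which is what
    lets a pooled PCA split into a forward and a vertical component instead
    of a single overall-size component.  Numeric values are plausible
    magnitudes only, not measurements.
    """
    between = StrideSpread(0.16, 0.034, 0.011, 0.017, 0.04, 0.006, 0.010)
    within = StrideSpread(0.025, 0.006, 0.002, 0.004, 0.02, 0.008, 0.010)
    means = {
        "healthy_young": StrideParams(1.42, 0.162, 0.046, 0.078, 1.00, 0.60, 0.80),
        "healthy_older": StrideParams(1.26, 0.126, 0.037, 0.060, 1.06, 0.62, 0.80),
        "mild_pd": StrideParams(1.12, 0.192, 0.055, 0.092, 1.10, 0.63, 0.80),
        "advanced_pd": StrideParams(0.92, 0.096, 0.028, 0.048, 1.16, 0.65, 0.80),
    }
    return {
        g: GroupProfile(g, means[g], between_subject_sd=between, within_subject_sd=within)
        for g in GROUPS
    }


# ---------------------------------------------------------------------------
# Piecewise-polynomial channel assembly
# ---------------------------------------------------------------------------

_DEG = 6  # max polynomial degree used by any segment


def _pad(coeffs_low: Sequence[float]) -> np.ndarray:
    """Low-first coefficient list -> fixed-length high-first column."""
    c = np.zeros(_DEG + 1)
    c[: len(coeffs_low)] = coeffs_low
    return c[::-1]


def _seg_const(y: float) -> np.ndarray:
    return _pad([y])


def _seg_smoothstep(h: float, y0: float, y1: float) -> np.ndarray:
    # y0 + (y1-y0) * (10u^3 - 15u^4 + 6u^5), u = x/h
    d = y1 - y0
    return _pad([y0, 0.0, 0.0, 10 * d / h**3, -15 * d / h**4, 6 * d / h**5])


def _seg_cubic_about(a: float, y_at_a: float, beta: float) -> np.ndarray:
    # y_at_a + beta * (x - a)^3
    return _pad(
        [y_at_a - beta * a**3, 3 * beta * a**2, -3 * beta * a, beta]
    )


def _seg_hermite5(h, y0, v0, a0, y1, v1, a1) -> np.ndarray:
    """Quintic matching value/rate/acceleration at both ends."""
    lhs = np.zeros((6, 6))
    for j in range(6):
        lhs[0, j] = 1.0 if j == 0 else 0.0
        lhs[1, j] = 1.0 if j == 1 else 0.0
        lhs[2, j] = 2.0 if j == 2 else 0.0
        lhs[3, j] = h**j
        lhs[4, j] = j * h ** (j - 1) if j >= 1 else 0.0
        lhs[5, j] = j * (j - 1) * h ** (j - 2) if j >= 2 else 0.0
    rhs = np.array([y0, v0, a0, y1, v1, a1], dtype=float)
    return _pad(np.linalg.solve(lhs, rhs))


def _bump6(h: float, amplitude: float) -> np.ndarray:
    # amplitude * 64 u^3 (1-u)^3 : C^2-flat at both ends, peak `amplitude`.
    a = 64.0 * amplitude
    u = np.array([0.0, 0.0, 0.0, 1.0, -3.0, 3.0, -1.0]) * a
    return _pad([u[j] / h**j for j in range(7)])


class _ChannelBuilder:
    """Accumulates contiguous polynomial segments into a scipy PPoly."""

    def __init__(self, t0: float = 0.0):
        self.breaks = [t0]
        self.cols: list[np.ndarray] = []

    @property
    def t(self) -> float:
        return self.breaks[-1]

    def add(self, h: float, col: np.ndarray):
        if h <= 0:
            raise ValueError("segment duration must be > 0")
        self.breaks.append(self.breaks[-1] + h)
        self.cols.append(col)

    def build(self) -> PPoly:
        c = np.column_stack(self.cols)
        return PPoly(c, np.asarray(self.breaks))


# ---------------------------------------------------------------------------
# World-frame kinematics
# ---------------------------------------------------------------------------

@dataclass
class WorldKinematics:
    """Sampled world-frame ankle kinematics for one leg.

    ``position`` columns are (x forward-of-start, y lateral, z up); the
    gravity vector is (0, 0, -g).  ``heading`` is the walking azimuth used
    to render turns.
    """

    time: np.ndarray
    position: np.ndarray  # (n, 3)
    velocity: np.ndarray  # (n, 3)
    acceleration: np.ndarray  # (n, 3)
    pitch: np.ndarray  # (n,)
    pitch_rate: np.ndarray
    heading: np.ndarray
    heading_rate: np.ndarray
    hs_times: np.ndarray  # heel-strike instants, seconds
    fs: float
    side: str = "left"


@dataclass
class StrideTruth:
    """Per-stride ground-truth record."""

    index: int
    side: str
    start_t: float
    end_t: float
    params: StrideParams
    is_turn: bool = False
    is_initial: bool = False
    is_final: bool = False
    # absolute event times (s)
    mid_stance_t: float = 0.0
    toe_off_t: float = 0.0
    max_clearance_t: float = 0.0
    support_change_t: float = 0.0
    features: dict[str, float] | None = None


@dataclass
class SessionTruth:
    participant_id: str
    group: str
    seed: int
    strides: dict[str, list[StrideTruth]]  # per side
    kinematics: dict[str, WorldKinematics] | None = None  # in-memory only

    def heel_strikes(self, side: str) -> np.ndarray:
        recs = self.strides[side]
        if not recs:
            return np.array([])
        return np.array([r.start_t for r in recs] + [recs[-1].end_t])

    def toe_offs(self, side: str) -> np.ndarray:
        return np.array([r.toe_off_t for r in self.strides[side]])

    def to_json_dict(self) -> dict:
        out = {
            "participant_id": self.participant_id,
            "group": self.group,
            "seed": self.seed,
            "strides": {},
        }
        for side, recs in self.strides.items():
            out["strides"][side] = [
                {
                    "index": r.index,
                    "start_t": r.start_t,
                    "end_t": r.end_t,
                    "params": asdict(r.params),
                    "flags": {
                        "turn": r.is_turn,
                        "initial": r.is_initial,
                        "final": r.is_final,
                    },
                    "events": {
                        "heel_strike_t": r.start_t,
                        "mid_stance_t": r.mid_stance_t,
                        "toe_off_t": r.toe_off_t,
                        "max_clearance_t": r.max_clearance_t,
                        "support_change_t": r.support_change_t,
                        "terminal_heel_strike_t": r.end_t,
                    },
                    "features": r.features,
                }
                for r in recs
            ]
        return out


def _leg_channels(
    stride_list: list[tuple[StrideParams, bool]],
    lead: float,
    tail: float,
    start_heading: float = 0.0,
):
    """Assemble z / path-progress / heading / pitch PPoly channels.

    Returns the four PPoly objects plus heel-strike times (stride
    boundaries) and the per-stride absolute anchor times.
    """
    zb = _ChannelBuilder()
    sb = _ChannelBuilder()
    hb = _ChannelBuilder()
    pb = _ChannelBuilder()

    # --- lead-in stand -----------------------------------------------------
    first_params = stride_list[0][0]
    ph0 = first_params.phases()
    T0 = first_params.stride_duration
    beta0 = _STANCE_ROTATION / (ph0["t_ms"] ** 3 + (ph0["t_ho"] - ph0["t_ms"]) ** 3)
    pitch_at_hs0 = -beta0 * ph0["t_ms"] ** 3
    rate_at_hs0 = 3 * beta0 * ph0["t_ms"] ** 2
    acc_at_hs0 = -6 * beta0 * ph0["t_ms"]
    if lead > _RAMP:
        pb.add(lead - _RAMP, _seg_const(pitch_at_hs0))
    pb.add(_RAMP, _seg_hermite5(_RAMP, pitch_at_hs0, 0, 0, pitch_at_hs0, rate_at_hs0, acc_at_hs0))
    zb.add(lead, _seg_const(0.0))
    sb.add(lead, _seg_const(0.0))
    hb.add(lead, _seg_const(start_heading))

    hs_times = [lead]
    anchors = []
    z_prev = 0.0
    s_level = 0.0
    heading = start_heading

    for params, is_turn in stride_list:
        ph = params.phases()
        T = params.stride_duration
        t0 = zb.t
        t_drop, t_ms, t_ho = ph["t_drop"], ph["t_ms"], ph["t_ho"]
        t_to, t_mc = ph["t_to"], ph["t_mc"]
        # terminal rest plateau: the ankle point comes to rest slightly
        # before the terminal heel strike and stays at rest through it, so
        # the zero-endpoint-velocity assumption holds in a neighbourhood of
        # every stride boundary (robust to +-few-sample segmentation error)
        t_rest = ph["t_rest"]

        # vertical: heel-off rise, toe-off dwell, then an ascent/descent
        # pair joined with matched (negative) curvature at the clearance
        # peak so the maximum is sharply localized
        t_a, t_b = ph["t_to_start"], ph["t_to_end"]
        h_to, h_mc, h_t = params.toe_off_height, params.max_clearance, params.terminal_height
        w1, w2 = t_mc - t_b, t_rest - t_mc
        c_peak = 4.0 * min((h_mc - h_to) / w1**2, (h_mc - h_t) / w2**2)
        c_peak = max(c_peak, 0.0)
        zb.add(t_drop, _seg_smoothstep(t_drop, z_prev, 0.0))
        zb.add(t_ho - t_drop, _seg_const(0.0))
        zb.add(t_a - t_ho, _seg_smoothstep(t_a - t_ho, 0.0, h_to))
        zb.add(t_b - t_a, _seg_const(h_to))
        zb.add(w1, _seg_hermite5(w1, h_to, 0.0, 0.0, h_mc, 0.0, -c_peak))
        zb.add(w2, _seg_hermite5(w2, h_mc, 0.0, -c_peak, h_t, 0.0, 0.0))
        zb.add(T - t_rest, _seg_const(h_t))
        z_prev = h_t

        # path progress: a slow pre-swing advance up to toe-off (ending at
        # zero velocity, so the toe-off feature read is robust to small
        # event-timing error) followed by the main swing sigmoid
        f1 = _F1_FRACTION * params.stride_length
        sb.add(t_ho, _seg_const(s_level))
        sb.add(t_a - t_ho, _seg_smoothstep(t_a - t_ho, s_level, s_level + f1))
        sb.add(t_b - t_a, _seg_const(s_level + f1))
        sb.add(t_rest - t_b, _seg_smoothstep(t_rest - t_b, s_level + f1,
                                             s_level + params.stride_length))
        sb.add(T - t_rest, _seg_const(s_level + params.stride_length))
        s_level += params.stride_length

        # heading: pi increment during the middle of a turn stride
        if is_turn:
            hb.add(0.2 * T, _seg_const(heading))
            hb.add(0.6 * T, _seg_smoothstep(0.6 * T, heading, heading + math.pi))
            heading += math.pi
            hb.add(0.2 * T, _seg_const(heading))
        else:
            hb.add(T, _seg_const(heading))

        # pitch: cubic about mid-stance in stance, Hermite + bump in swing
        beta = _STANCE_ROTATION / (t_ms**3 + (t_ho - t_ms) ** 3)
        pb.add(t_ho, _seg_cubic_about(t_ms, 0.0, beta))
        theta_a = beta * (t_ho - t_ms) ** 3
        v_a = 3 * beta * (t_ho - t_ms) ** 2
        a_a = 6 * beta * (t_ho - t_ms)
        theta_end = -beta * t_ms**3
        v_end = 3 * beta * t_ms**2
        a_end = -6 * beta * t_ms
        h_sw = T - t_ho
        bump_amp = _SWING_BUMP * (0.4 if is_turn else 1.0)
        col = _seg_hermite5(h_sw, theta_a, v_a, a_a, theta_end, v_end, a_end)
        col = col + _bump6(h_sw, bump_amp)
        pb.add(h_sw, col)

        hs_times.append(zb.t)
        anchors.append(
            {
                "start_t": t0,
                "end_t": zb.t,
                "mid_stance_t": t0 + t_ms,
                "toe_off_t": t0 + t_to,
                "max_clearance_t": t0 + t_mc,
            }
        )

    # --- tail stand --------------------------------------------------------
    last_params = stride_list[-1][0]
    phL = last_params.phases()
    betaL = _STANCE_ROTATION / (phL["t_ms"] ** 3 + (phL["t_ho"] - phL["t_ms"]) ** 3)
    pitch_hs = -betaL * phL["t_ms"] ** 3
    rate_hs = 3 * betaL * phL["t_ms"] ** 2
    acc_hs = -6 * betaL * phL["t_ms"]
    pb.add(_RAMP, _seg_hermite5(_RAMP, pitch_hs, rate_hs, acc_hs, pitch_hs, 0, 0))
    if tail > _RAMP:
        pb.add(tail - _RAMP, _seg_const(pitch_hs))
    # settle to foot-flat, then hold (constant final segment so that PPoly
    # extrapolation beyond this leg's span stays flat)
    drop = min(0.3, 0.5 * tail)
    zb.add(drop, _seg_smoothstep(drop, z_prev, 0.0))
    zb.add(tail - drop, _seg_const(0.0))
    sb.add(tail, _seg_const(s_level))
    hb.add(tail, _seg_const(heading))

    return zb.build(), sb.build(), hb.build(), pb.build(), np.array(hs_times), anchors


def _sample_kinematics(z, s, h, p, span: float, fs: float, hs_times, side: str) -> WorldKinematics:
    n = int(round(span * fs)) + 1
    t = np.arange(n) / fs
    zv, zd1, zd2 = z(t), z.derivative()(t), z.derivative(2)(t)
    sd1, sd2 = s.derivative()(t), s.derivative(2)(t)
    psi, psid1 = h(t), h.derivative()(t)
    pitch, pitch_rate = p(t), p.derivative()(t)

    cos_p, sin_p = np.cos(psi), np.sin(psi)
    vel = np.column_stack([sd1 * cos_p, sd1 * sin_p, zd1])
    acc = np.column_stack(
        [
            sd2 * cos_p - sd1 * psid1 * sin_p,
            sd2 * sin_p + sd1 * psid1 * cos_p,
            zd2,
        ]
    )
    # horizontal position by trapezoidal quadrature of the analytic velocity
    dt = 1.0 / fs
    pos_xy = np.zeros((n, 2))
    pos_xy[1:] = np.cumsum(0.5 * dt * (vel[1:, :2] + vel[:-1, :2]), axis=0)
    position = np.column_stack([pos_xy, zv])
    return WorldKinematics(
        time=t,
        position=position,
        velocity=vel,
        acceleration=acc,
        pitch=pitch,
        pitch_rate=pitch_rate,
        heading=psi,
        heading_rate=psid1,
        hs_times=np.asarray(hs_times, dtype=float),
        fs=fs,
        side=side,
    )


def simulate_stride_kinematics(params: StrideParams, fs: float) -> WorldKinematics:
    """World-frame kinematics of a single isolated stride (no stands).

    The returned series spans ``[0, stride_duration]`` inclusive; forward
    position rises from 0 to ``stride_length``, vertical position from 0
    through ``toe_off_height`` (at the stance fraction) and
    ``max_clearance`` (at the clearance phase) to ``terminal_height``.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    lead = tail = 1.0
    z, s, h, p, hs, anchors = _leg_channels([(params, False)], lead, tail)
    T = params.stride_duration
    n = int(round(T * fs)) + 1
    t = np.arange(n) / fs + lead
    kin = _sample_kinematics(z, s, h, p, lead + T + tail, fs, hs, "left")
    i0 = int(round(lead * fs))
    sl = slice(i0, i0 + n)
    out = WorldKinematics(
        time=kin.time[sl] - lead,
        position=kin.position[sl] - kin.position[i0],
        velocity=kin.velocity[sl],
        acceleration=kin.acceleration[sl],
        pitch=kin.pitch[sl],
        pitch_rate=kin.pitch_rate[sl],
        heading=kin.heading[sl],
        heading_rate=kin.heading_rate[sl],
        hs_times=np.array([0.0, T]),
        fs=fs,
    )
    return out


def orientation_series(kin: WorldKinematics) -> Rotation:
    """True sensor->world rotation at each sample."""
    n = len(kin.time)
    rz = Rotation.from_euler("z", kin.heading[:, None])
    ry = Rotation.from_euler("y", kin.pitch[:, None])
    return rz * ry * Rotation.from_matrix(np.broadcast_to(R0, (n, 3, 3)))


def render_imu(
    kin: WorldKinematics,
    noise: SensorNoise | None = None,
    seed: int | np.random.SeedSequence = 0,
    spec: SensorSpec | None = None,
) -> ImuSeries:
    """Render world kinematics into a sensor-frame ImuSeries.

    The accelerometer reads the specific force ``R^T (a_world + g z_hat)``;
    the gyroscope reads the body angular rate, plus an additive raised-cosine
    transient on the sagittal channel at each heel strike, plus constant bias
    and white noise.  Deterministic for a fixed seed.
    """
    noise = noise or SensorNoise()
    spec = spec or SensorSpec(sampling_rate=kin.fs)
    rng = np.random.default_rng(seed)
    n = len(kin.time)

    # Heel-strike transient: a short zero-net pitch oscillation (impact
    # wiggle) at each heel strike.  It is applied to BOTH the orientation
    # used to project gravity and the gyroscope output, i.e. it is real
    # (self-consistent) motion, not an additive artefact — a strapdown
    # estimator integrates through it exactly, while an event detector sees
    # a sharp spike on the sagittal channel.
    w = noise.hs_spike_width
    theta_amp = noise.hs_spike_amplitude * w / 3.4346  # peak rate -> angle
    pitch_j = np.zeros(n)
    rate_j = np.zeros(n)
    for t_hs in kin.hs_times:
        # support placed so the first (positive, on the sensor channel)
        # rate lobe peaks exactly at the heel-strike instant
        u = (kin.time - (t_hs - 0.27639 * w)) / w
        m = (u > 0) & (u < 1)
        if not np.any(m):
            continue
        um = u[m]
        b = 64.0 * um**3 * (1 - um) ** 3
        db = 64.0 * 3 * um**2 * (1 - um) ** 2 * (1 - 2 * um) / w
        pitch_j[m] += -theta_amp * b
        rate_j[m] += -theta_amp * db

    pitch = kin.pitch + pitch_j
    pitch_rate = kin.pitch_rate + rate_j
    rz = Rotation.from_euler("z", kin.heading[:, None])
    ry = Rotation.from_euler("y", pitch[:, None])
    rot = rz * ry * Rotation.from_matrix(np.broadcast_to(R0, (n, 3, 3)))
    inv = rot.inv()
    g_vec = np.array([0.0, 0.0, GRAVITY])
    accel_s = inv.apply(kin.acceleration + g_vec)

    # angular velocity: omega_w = psi_dot z_hat + pitch_rate * Rz(psi) y_hat
    y_rot = np.column_stack([-np.sin(kin.heading), np.cos(kin.heading), np.zeros(n)])
    omega_w = kin.heading_rate[:, None] * np.array([0.0, 0.0, 1.0]) + (
        pitch_rate[:, None] * y_rot
    )
    gyro_s = inv.apply(omega_w)

    accel_s = accel_s + np.asarray(noise.accel_bias)
    gyro_s = gyro_s + np.asarray(noise.gyro_bias)
    if noise.accel_noise_sd > 0:
        accel_s += rng.normal(0.0, noise.accel_noise_sd, size=(n, 3))
    if noise.gyro_noise_sd > 0:
        gyro_s += rng.normal(0.0, noise.gyro_noise_sd, size=(n, 3))

    # physical sensor saturation at the configured full scale (rare: only
    # the fastest swing peaks of the longest strides come close)
    accel_s = np.clip(accel_s, -spec.accel_range, spec.accel_range)
    gyro_s = np.clip(gyro_s, -spec.gyro_range, spec.gyro_range)

    return ImuSeries(side=kin.side, time=kin.time.copy(), accel=accel_s, gyro=gyro_s)


# ---------------------------------------------------------------------------
# Sessions and cohorts
# ---------------------------------------------------------------------------

def _clip_assemble(value: dict[str, float]) -> StrideParams:
    stance = float(np.clip(value["stance_fraction"], 0.45, 0.75))
    clear = float(np.clip(value["clearance_phase"], stance + 0.05, 0.95))
    mc = float(np.clip(value["max_clearance"], 0.02, 0.40))
    return StrideParams(
        stride_length=float(np.clip(value["stride_length"], 0.05, 2.5)),
        max_clearance=mc,
        toe_off_height=min(float(np.clip(value["toe_off_height"], 0.0, 0.30)), 0.9 * mc),
        terminal_height=min(float(np.clip(value["terminal_height"], 0.0, 0.30)), 0.9 * mc),
        stride_duration=float(np.clip(value["stride_duration"], 0.5, 2.5)),
        stance_fraction=stance,
        clearance_phase=clear,
    )


def _draw_params(mean: StrideParams, sd: StrideSpread, rng) -> StrideParams:
    """Independent Gaussian draw around `mean`, clipped into validity."""
    raw = {
        name: getattr(mean, name) + getattr(sd, name) * rng.standard_normal()
        if getattr(sd, name) > 0 else getattr(mean, name)
        for name in asdict(mean)
    }
    return _clip_assemble(raw)


# Between-subject structure: a forward-size factor drives stride length and
# a vertical-size factor drives the three heights.  The factors are
# negatively correlated (individuals with shorter forward extent tend to
# lift the foot more — the compensation pattern the cohorts exhibit), which
# offsets the positive forward/vertical covariance the group means induce
# and lets the pooled PCA separate a forward from a vertical component.
_FACTOR_LOADING_F = 0.92
_FACTOR_LOADING_V = 0.45
_FACTOR_CORR = -0.55


def _draw_subject_mean(mean: StrideParams, sd: StrideSpread, rng) -> StrideParams:
    """Between-subject draw with correlated forward / vertical factors."""
    f_lat = rng.standard_normal()
    v_lat = _FACTOR_CORR * f_lat + math.sqrt(1.0 - _FACTOR_CORR**2) * rng.standard_normal()
    loading = {
        "stride_length": (_FACTOR_LOADING_F, f_lat),
        "toe_off_height": (_FACTOR_LOADING_V, v_lat),
        "max_clearance": (_FACTOR_LOADING_V, v_lat),
        "terminal_height": (_FACTOR_LOADING_V, v_lat),
    }
    raw = {}
    for name in asdict(mean):
        m, s = getattr(mean, name), getattr(sd, name)
        if s <= 0:
            raw[name] = m
        elif name in loading:
            lam, latent = loading[name]
            resid = math.sqrt(1.0 - lam**2)
            raw[name] = m + s * (lam * latent + resid * rng.standard_normal())
        else:
            raw[name] = m + s * rng.standard_normal()
    return _clip_assemble(raw)


_TURN_PARAMS = dict(
    stride_length=0.08,
    max_clearance=0.045,
    toe_off_height=0.018,
    terminal_height=0.018,
    stance_fraction=0.60,
    clearance_phase=0.80,
)


def _true_features(params: StrideParams, phases: dict[str, float]) -> dict[str, float]:
    """Analytic F1-F3 / V1-V3 under the package's default event conventions.

    Forward displacements are referenced to the stride-onset heel strike,
    vertical displacements to the mid-stance (foot-flat) level.  The
    support-change instant is the contralateral toe-off following the
    terminal heel strike, clamped into the stride window (= the terminal
    heel strike for half-cycle-offset legs).
    """
    s5 = lambda x: 10 * x**3 - 15 * x**4 + 6 * x**5
    f1 = _F1_FRACTION * params.stride_length
    u2 = (phases["t_mc"] - phases["t_to_end"]) / (phases["t_rest"] - phases["t_to_end"])
    f2 = params.stride_length * (_F1_FRACTION + (1 - _F1_FRACTION) * s5(u2))
    return {
        "F1": f1,
        "F2": f2,
        "F3": params.stride_length,
        "V1": params.toe_off_height,
        "V2": params.max_clearance,
        "V3": params.terminal_height,
    }


def simulate_session(
    profile: GroupProfile,
    spec: CohortSpec | None = None,
    phase_offset: float = 0.5,
    seed: int | np.random.SeedSequence = 0,
    participant_id: str = "p000",
    noise: SensorNoise | None = None,
    keep_kinematics: bool = True,
    render: bool = True,
) -> tuple[WalkSession, SessionTruth]:
    """Simulate one participant's back-and-forth walk on both legs.

    The right leg runs ``phase_offset`` of a stride cycle behind the left;
    both legs share the session clock.  Turn strides at the configured
    indices are rendered as low-amplitude strides with a pi heading change
    and flagged in ground truth.  Reproducible for a fixed seed.
    """
    spec = spec or CohortSpec()
    noise = noise if noise is not None else SensorNoise()
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    draw_ss, render_ss_l, render_ss_r = ss.spawn(3)
    rng = np.random.default_rng(draw_ss)

    # participant-level mean: correlated between-subject draw
    subj_mean = _draw_subject_mean(profile.mean, profile.between_subject_sd, rng)
    turn_idx = set(spec.resolved_turn_indices())
    n_str = spec.strides_per_session

    def leg_strides() -> list[tuple[StrideParams, bool]]:
        out = []
        for k in range(n_str):
            if k in turn_idx:
                dur = 1.3 * subj_mean.stride_duration
                out.append((StrideParams(stride_duration=dur, **_TURN_PARAMS), True))
            else:
                out.append((_draw_params(subj_mean, profile.within_subject_sd, rng), False))
        return out

    strides_l = leg_strides()
    strides_r = leg_strides()

    lead_l = 1.2
    lead_r = lead_l + phase_offset * subj_mean.stride_duration

    built = {}
    for side, strides, lead, render_ss in (
        ("left", strides_l, lead_l, render_ss_l),
        ("right", strides_r, lead_r, render_ss_r),
    ):
        z, s, h, p, hs, anchors = _leg_channels(strides, lead, 1.2)
        built[side] = dict(z=z, s=s, h=h, p=p, hs=hs, anchors=anchors, strides=strides,
                           render_ss=render_ss)

    span = max(b["z"].x[-1] for b in built.values())
    sensor_spec = SensorSpec(sampling_rate=spec.sampling_rate)

    series = {}
    kins = {}
    for side, b in built.items():
        if render:
            kin = _sample_kinematics(
                b["z"], b["s"], b["h"], b["p"], span, spec.sampling_rate, b["hs"], side
            )
            kins[side] = kin
            series[side] = render_imu(kin, noise, seed=b["render_ss"], spec=sensor_spec)
        else:  # truth-only fast path; identical RNG consumption
            t2 = np.array([0.0, 1.0 / spec.sampling_rate])
            series[side] = ImuSeries(side=side, time=t2, accel=np.zeros((2, 3)),
                                     gyro=np.zeros((2, 3)))

    # ground-truth stride records, incl. the support-change instant derived
    # from the contralateral truth toe-offs
    truth_strides: dict[str, list[StrideTruth]] = {}
    for side in ("left", "right"):
        other = "right" if side == "left" else "left"
        contra_to = np.array(
            [a["toe_off_t"] for a in built[other]["anchors"]]
        )
        recs = []
        for k, ((params, is_turn), a) in enumerate(
            zip(built[side]["strides"], built[side]["anchors"])
        ):
            after = contra_to[contra_to > a["end_t"] + 1e-9]
            sc = min(after[0], a["end_t"]) if len(after) else a["end_t"]
            feats = None if is_turn else _true_features(params, params.phases())
            recs.append(
                StrideTruth(
                    index=k,
                    side=side,
                    start_t=a["start_t"],
                    end_t=a["end_t"],
                    params=params,
                    is_turn=is_turn,
                    is_initial=k < 5,
                    is_final=k >= n_str - 5,
                    mid_stance_t=a["mid_stance_t"],
                    toe_off_t=a["toe_off_t"],
                    max_clearance_t=a["max_clearance_t"],
                    support_change_t=sc,
                    features=feats,
                )
            )
        truth_strides[side] = recs

    session = WalkSession(
        participant_id=participant_id,
        group=profile.group,
        left=series["left"],
        right=series["right"],
        spec=sensor_spec,
    )
    truth = SessionTruth(
        participant_id=participant_id,
        group=profile.group,
        seed=int(np.random.default_rng(draw_ss).integers(2**31)),
        strides=truth_strides,
        kinematics=kins if keep_kinematics else None,
    )
    return session, truth


def simulate_cohort(
    profiles: dict[str, GroupProfile] | None = None,
    spec: CohortSpec | None = None,
    noise: SensorNoise | None = None,
    keep_kinematics: bool = False,
    render: bool = True,
):
    """Simulate one session per participant across the configured groups.

    Returns ``(sessions, truth_table)`` where ``sessions`` is a list of
    ``(WalkSession, SessionTruth)`` and ``truth_table`` is a pandas
    DataFrame of per-participant mean true features over the strides the
    selection protocol would retain.
    """
    import pandas as pd

    from .gait_features import StrideFlags, select_strides

    profiles = profiles or make_default_profiles()
    spec = spec or CohortSpec()
    root = np.random.SeedSequence(spec.seed)

    sessions = []
    rows = []
    pid = 0
    for group in GROUPS:
        count = spec.counts.get(group, 0)
        for _ in range(count):
            child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(pid,))
            session, truth = simulate_session(
                profiles[group],
                spec,
                seed=child,
                participant_id=f"p{pid:03d}",
                noise=noise,
                keep_kinematics=keep_kinematics,
                render=render,
            )
            sessions.append((session, truth))

            feats: dict[str, list[float]] = {k: [] for k in ("F1", "F2", "F3", "V1", "V2", "V3")}
            n_sel = 0
            for side in ("left", "right"):
                recs = truth.strides[side]
                flags = [
                    StrideFlags(turn=r.is_turn, initial=r.is_initial, final=r.is_final)
                    for r in recs
                ]
                sel = select_strides(flags)
                for r, keep in zip(recs, sel.selected):
                    if keep and r.features is not None:
                        n_sel += 1
                        for k, v in r.features.items():
                            feats[k].append(v)
            row = {"participant_id": f"p{pid:03d}", "group": group, "n_strides": n_sel}
            row.update({k: float(np.mean(v)) if v else np.nan for k, v in feats.items()})
            rows.append(row)
            pid += 1

    truth_table = pd.DataFrame(
        rows, columns=["participant_id", "group", "F1", "F2", "F3", "V1", "V2", "V3", "n_strides"]
    )
    return sessions, truth_table


def write_session(session: WalkSession, truth: SessionTruth, out_dir: str | Path) -> dict:
    """Write the session CSVs plus a ``<participant>.truth.json`` sidecar."""
    out_dir = Path(out_dir)
    paths = session_to_csv(session, out_dir)
    truth_path = out_dir / f"{session.participant_id}.truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
    return {"left": paths["left"], "right": paths["right"], "truth": truth_path}
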