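"""Stride-by-stride strapdown foot-trajectory estimation from shank IMU data.

Pipeline per leg: detect heel strikes from the spike signature on the
sagittal gyro channel, cut the series into heel-strike-to-heel-strike
strides, anchor orientation to gravity at the quietest in-stance instant
(minimum pitch-rate magnitude), propagate orientation with the gyroscope
outward from that anchor, rotate acceleration into the world frame, remove
gravity, and doubly integrate under zero-endpoint constraints with a
forward/backward weighted average that cancels constant drift.  Each stride
is processed independently so integration error cannot accumulate across
strides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

from .imu_io import GRAVITY, ImuSeries, WalkSession

logger = logging.getLogger(__name__)


class EstimationError(ValueError):
    pass


class NotQuasiStaticError(EstimationError):
    """Mid-stance accelerometer norm too far from 1 g."""


class DegenerateStrideError(EstimationError):
    """Net horizontal displacement too small to define a forward axis."""


@dataclass(frozen=True)
class DetectorConfig:
    """Heel-strike spike detector settings."""

    band_hz: tuple[float, float] = (0.5, 15.0)
    mad_k: float = 4.0  # adaptive threshold = k * MAD of the filtered channel
    min_stride_time: float = 0.6  # s, refractory period
    polarity: str = "positive"  # which spike sign to pick ("positive"|"negative"|"abs")


@dataclass(frozen=True)
class EstimatorConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    #: mid-stance search window as fractions of the stride
    midstance_window: tuple[float, float] = (0.05, 0.5)
    #: accel-norm tolerance (in g) for the gravity-only anchor
    quasi_static_tolerance: tuple[float, float] = (0.8, 1.2)
    #: half-width (samples) of the accel average taken at the anchor
    anchor_halfwidth: int = 3
    #: weight function for forward/backward blending ("linear"|"smoothstep")
    weight: str = "linear"
    #: minimum net horizontal displacement for a usable stride (m)
    min_displacement: float = 1e-3
    #: "heelstrike" windows (default) or "midstance" windows
    segmentation: str = "heelstrike"


@dataclass
class StrideSegment:
    """Half-open sample window ``[start, end)`` of one stride."""

    side: str
    start_index: int
    end_index: int
    heel_strike_index: int
    mid_stance_index: int

    def __post_init__(self):
        if not (self.start_index < self.end_index):
            raise ValueError("start_index must be < end_index")
        for name in ("heel_strike_index", "mid_stance_index"):
            v = getattr(self, name)
            if not (self.start_index <= v < self.end_index):
                raise ValueError(f"{name} must lie inside [start, end)")

    def __len__(self):
        return self.end_index - self.start_index


@dataclass
class StrideTrajectory:
    """Estimated ankle-point path of one stride in a stride-local frame.

    Position columns are (forward, lateral, vertical) in metres; ``time``
    is seconds from the stride-onset heel strike.  By construction
    ``position[0] == 0``, the velocity vanishes at both ends and the
    vertical channel is zero at both ends.
    """

    time: np.ndarray
    position: np.ndarray  # (n, 3)
    velocity: np.ndarray  # (n, 3)
    forward_azimuth: float = 0.0  # world azimuth of the forward axis, rad

    @property
    def stride_length(self) -> float:
        return float(self.position[-1, 0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


# ---------------------------------------------------------------------------
# Event detection and segmentation
# ---------------------------------------------------------------------------

def detect_heel_strikes(
    gyro_sagittal: np.ndarray,
    fs: float,
    config: DetectorConfig | None = None,
) -> np.ndarray:
    """Locate heel-strike spikes on the sagittal gyro channel.

    Band-passes the channel, thresholds at ``mad_k`` times the median
    absolute deviation, and keeps one local maximum per refractory period
    (the larger peak wins within ``min_stride_time``).  Returns strictly
    increasing sample indices; may be empty.
    """
    config = config or DetectorConfig()
    x = np.asarray(gyro_sagittal, dtype=float)
    if len(x) <= 2 * fs:
        raise ValueError("series too short for heel-strike detection (< ~2 s)")

    lo, hi = config.band_hz
    hi = min(hi, 0.49 * fs)
    sos = butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    f = sosfiltfilt(sos, x)
    if config.polarity == "negative":
        f = -f
    elif config.polarity == "abs":
        f = np.abs(f)

    scale = np.median(np.abs(f - np.median(f))) / 0.6744897501960817  # MAD -> sigma
    if scale == 0:
        scale = float(f.std())  # sparse-spike signals have zero MAD
    threshold = config.mad_k * scale
    if threshold <= 0:
        return np.array([], dtype=int)

    above = f > threshold
    if not np.any(above):
        return np.array([], dtype=int)

    # candidate peaks: local maxima of f within above-threshold runs
    idx = np.flatnonzero(above)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    candidates = [int(r[np.argmax(f[r])]) for r in runs if len(r)]
    candidates.sort()

    refractory = int(round(config.min_stride_time * fs))
    kept: list[int] = []
    for c in candidates:
        if kept and c - kept[-1] < refractory:
            if f[c] > f[kept[-1]]:
                kept[-1] = c
        else:
            kept.append(c)
    return np.array(kept, dtype=int)


def segment_strides(
    series: ImuSeries,
    heel_strikes: Sequence[int],
    config: EstimatorConfig | None = None,
) -> list[StrideSegment]:
    """One segment per consecutive heel-strike pair.

    Each segment records its integration anchor ``mid_stance_index``: the
    sample of minimum pitch-rate magnitude inside the configured in-stance
    search window.  Returns an empty list for fewer than two heel strikes.
    """
    config = config or EstimatorConfig()
    hs = np.asarray(heel_strikes, dtype=int)
    if len(hs) < 2:
        return []
    lo_f, hi_f = config.midstance_window
    pitch_rate = series.gyro[:, 2]
    segments = []
    for a, b in zip(hs[:-1], hs[1:]):
        n = b - a
        w0 = a + max(1, int(round(lo_f * n)))
        w1 = a + max(w0 - a + 1, int(round(hi_f * n)))
        ms = w0 + int(np.argmin(np.abs(pitch_rate[w0:w1])))
        segments.append(
            StrideSegment(
                side=series.side,
                start_index=int(a),
                end_index=int(b),
                heel_strike_index=int(a),
                mid_stance_index=int(ms),
            )
        )
    return segments


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def estimate_initial_orientation(
    accel_at_midstance: np.ndarray,
    tolerance: tuple[float, float] = (0.8, 1.2),
) -> Rotation:
    """Gravity-aligned sensor->world rotation at the quasi-static anchor.

    Maps the measured specific-force vector onto world ``(0, 0, +g)``.
    The unobservable yaw is fixed so that the sensor sagittal axis (z) maps
    into the world lateral axis; any residual azimuth is absorbed later by
    the stride-frame rotation.
    """
    a = np.asarray(accel_at_midstance, dtype=float)
    norm = float(np.linalg.norm(a))
    if not (tolerance[0] * GRAVITY <= norm <= tolerance[1] * GRAVITY):
        raise NotQuasiStaticError(
            f"|accel| = {norm:.3f} m/s^2 outside [{tolerance[0]:.2f}, "
            f"{tolerance[1]:.2f}] g: bad mid-stance anchor"
        )
    up = a / norm
    # tilt: shortest rotation taking the measured direction to world +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(up, z)
    s = np.linalg.norm(v)
    c = float(np.dot(up, z))
    if s < 1e-12:
        tilt = Rotation.identity() if c > 0 else Rotation.from_rotvec([np.pi, 0, 0])
    else:
        axis = v / s
        tilt = Rotation.from_rotvec(axis * np.arctan2(s, c))
    # yaw: map the sensor sagittal axis (z) into the world lateral (y) axis
    lat = tilt.apply([0.0, 0.0, 1.0])
    yaw = np.arctan2(lat[0], -lat[1])  # rotate so x-component vanishes, y < 0
    return Rotation.from_euler("z", yaw) * tilt


def propagate_orientation(
    gyro: np.ndarray,
    init: Rotation,
    mid_stance_index: int,
    fs: float,
) -> Rotation:
    """Integrate body rates outward (both directions) from the anchor.

    First-order rotation-vector exponential per step with midpoint rates;
    per-sample quaternion renormalization.  Returns a Rotation holding one
    orientation per input sample.
    """
    omega = np.asarray(gyro, dtype=float)
    n = len(omega)
    if not (0 <= mid_stance_index < n):
        raise ValueError("mid_stance_index outside series")
    dt = 1.0 / fs
    mid = 0.5 * (omega[1:] + omega[:-1]) * dt  # incremental rotation vectors

    def qmul(q1, q2):
        x1, y1, z1, w1 = q1
        x2, y2, z2, w2 = q2
        return np.array(
            [
                w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
                w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            ]
        )

    incr = Rotation.from_rotvec(mid).as_quat() if n > 1 else np.empty((0, 4))
    quats = np.empty((n, 4))
    quats[mid_stance_index] = init.as_quat()
    for k in range(mid_stance_index, n - 1):
        q = qmul(quats[k], incr[k])
        quats[k + 1] = q / np.linalg.norm(q)
    for k in range(mid_stance_index, 0, -1):
        # inverse step: q_{k-1} = q_k * conj(incr_{k-1})
        ci = incr[k - 1] * np.array([-1.0, -1.0, -1.0, 1.0])
        q = qmul(quats[k], ci)
        quats[k - 1] = q / np.linalg.norm(q)
    return Rotation.from_quat(quats)


def world_acceleration(
    accel: np.ndarray,
    orientation: Rotation,
    gravity: float = GRAVITY,
) -> np.ndarray:
    """Rotate sensor accel samples to the world frame and remove gravity."""
    a = np.asarray(accel, dtype=float)
    if len(a) != len(orientation):
        raise ValueError("accel and orientation lengths differ")
    return orientation.apply(a) - np.array([0.0, 0.0, gravity])


# ---------------------------------------------------------------------------
# De-drifted double integration
# ---------------------------------------------------------------------------

def _cumint0(y: np.ndarray, dt: float) -> np.ndarray:
    """Cumulative trapezoid integral from zero."""
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * dt * (y[1:] + y[:-1]), axis=0)
    return out


def dedrift_integrate(
    world_accel: np.ndarray,
    fs: float,
    weight: str = "linear",
) -> tuple[np.ndarray, np.ndarray]:
    """Doubly integrate one stride under zero-endpoint constraints.

    Velocity is the pointwise blend ``(1-w) v_f + w v_b`` of the forward
    integral (zero initial velocity) and backward integral (zero final
    velocity); with the default linear ramp ``w(t) = t/T`` a constant
    acceleration bias cancels exactly.  Position integrates the blended
    velocity from zero; the vertical channel is then linearly detrended so
    that it ends at zero (the zero-height constraint).
    """
    a = np.asarray(world_accel, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    n = len(a)
    if n < 4:
        raise EstimationError("stride too short to integrate (< 4 samples)")
    dt = 1.0 / fs
    v_f = _cumint0(a, dt)
    tau = np.linspace(0.0, 1.0, n)[:, None]
    if weight == "linear":
        w = tau
    elif weight == "smoothstep":
        w = tau * tau * (3 - 2 * tau)
    else:
        raise ValueError(f"unknown weight {weight!r}")
    # v_b(t) = v_f(t) - v_f(T) is the backward integral with v_b(T) = 0
    v = v_f - w * v_f[-1]
    p = _cumint0(v, dt)
    if p.shape[1] >= 3:
        p[:, 2] -= tau[:, 0] * p[-1, 2]
    return v, p


def rotate_to_stride_frame(
    time: np.ndarray,
    position: np.ndarray,
    velocity: np.ndarray,
    min_displacement: float = 1e-3,
) -> StrideTrajectory:
    """Rotate horizontal axes so 'forward' is the net-displacement azimuth."""
    d = position[-1, :2] - position[0, :2]
    r = float(np.hypot(*d))
    if r < min_displacement:
        raise DegenerateStrideError(
            f"net horizontal displacement {r * 1e3:.2f} mm < "
            f"{min_displacement * 1e3:.2f} mm (turn or standing?)"
        )
    az = float(np.arctan2(d[1], d[0]))
    c, s = np.cos(-az), np.sin(-az)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return StrideTrajectory(
        time=np.asarray(time) - time[0],
        position=position @ rot.T,
        velocity=velocity @ rot.T,
        forward_azimuth=az,
    )


# ---------------------------------------------------------------------------
# Whole-session driver
# ---------------------------------------------------------------------------

@dataclass
class DroppedStride:
    side: str
    start_index: int
    end_index: int
    reason: str


def estimate_stride(
    series: ImuSeries,
    segment: StrideSegment,
    fs: float,
    config: EstimatorConfig,
) -> StrideTrajectory:
    """Run the per-stride chain for one segment (raises on failure)."""
    # include the terminal heel-strike sample so the window spans [0, T]
    sl = slice(segment.start_index, min(segment.end_index + 1, len(series)))
    accel = series.accel[sl]
    gyro = series.gyro[sl]
    time = series.time[sl]
    anchor = segment.mid_stance_index - segment.start_index
    hw = config.anchor_halfwidth
    a_ms = accel[max(0, anchor - hw): anchor + hw + 1].mean(axis=0)
    init = estimate_initial_orientation(a_ms, config.quasi_static_tolerance)
    orient = propagate_orientation(gyro, init, anchor, fs)
    a_w = world_acceleration(accel, orient)
    vel, pos = dedrift_integrate(a_w, fs, weight=config.weight)
    return rotate_to_stride_frame(time, pos, vel, config.min_displacement)


def estimate_trajectories(
    session: WalkSession,
    config: EstimatorConfig | None = None,
) -> dict[str, dict]:
    """Estimate every stride trajectory in a session, per leg.

    Returns ``{side: {"segments": [...], "trajectories": [...],
    "dropped": [...]}}`` where segments/trajectories are parallel lists of
    the strides that survived all stages and ``dropped`` records the
    discarded ones with reasons.
    """
    config = config or EstimatorConfig()
    out: dict[str, dict] = {}
    for series in (session.left, session.right):
        fs = session.spec.sampling_rate
        result = {"segments": [], "trajectories": [], "dropped": []}
        try:
            hs = detect_heel_strikes(series.gyro[:, 2], fs, config.detector)
        except ValueError as e:
            logger.warning("%s: %s", series.side, e)
            out[series.side] = result
            continue
        segments = segment_strides(series, hs, config)
        if not segments:
            result["dropped"].append(
                DroppedStride(series.side, 0, len(series), "fewer than 2 heel strikes")
            )
            out[series.side] = result
            continue
        for seg in segments:
            try:
                traj = estimate_stride(series, seg, fs, config)
            except EstimationError as e:
                result["dropped"].append(
                    DroppedStride(series.side, seg.start_index, seg.end_index, str(e))
                )
                continue
            result["segments"].append(seg)
            result["trajectories"].append(traj)
        out[series.side] = result
    return out
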