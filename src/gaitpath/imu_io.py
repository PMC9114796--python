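"""Data model and CSV I/O for shank-worn IMU walking sessions.

Conventions
-----------
Sensor frame (at the reference upright posture): ``x`` forward, ``y`` up,
``z`` lateral (the sagittal rotation axis) — so the third gyroscope channel
carries the shank pitch rate.  All internal units are SI: metres, seconds,
radians.  The CSV dialect converts ``g`` / ``deg/s`` inputs at the boundary
when the header declares those units.

The canonical file layout is::

    # units: s,m/s^2,m/s^2,m/s^2,rad/s,rad/s,rad/s
    time_s,ax,ay,az,gx,gy,gz
    0.000000,0.123456789,...

one file per leg.  ``write_imu_csv`` always emits SI with fixed precision
(9 decimal places), which makes the round trip lossless to well below any
sensor resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

GRAVITY = 9.80665
"""Standard gravity (m/s^2) used everywhere in the package."""

G_PER_MS2 = 1.0 / GRAVITY
_DEG2RAD = np.pi / 180.0

_CSV_COLUMNS = ("time_s", "ax", "ay", "az", "gx", "gy", "gz")
_SI_UNITS = ("s", "m/s^2", "m/s^2", "m/s^2", "rad/s", "rad/s", "rad/s")

#: tolerance on uniform sampling, seconds
TIME_TOLERANCE = 1e-6


class ImuIoError(ValueError):
    """Base class for IMU parsing/validation errors."""


class MissingColumnError(ImuIoError):
    pass


class NonUniformSamplingError(ImuIoError):
    def __init__(self, msg: str, row: int):
        super().__init__(msg)
        self.row = row


class RangeExceededError(ImuIoError):
    def __init__(self, msg: str, row: int):
        super().__init__(msg)
        self.row = row


@dataclass(frozen=True)
class SensorSpec:
    """Static description of the IMU (ranges in device units)."""

    sampling_rate: float = 100.0  # Hz
    accel_range_g: float = 8.0
    gyro_range_dps: float = 1000.0
    gravity: float = GRAVITY

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.accel_range_g <= 0 or self.gyro_range_dps <= 0:
            raise ValueError("sensor ranges must be > 0")

    @property
    def accel_range(self) -> float:
        """Accelerometer full scale in m/s^2."""
        return self.accel_range_g * self.gravity

    @property
    def gyro_range(self) -> float:
        """Gyroscope full scale in rad/s."""
        return self.gyro_range_dps * _DEG2RAD


@dataclass
class ImuSeries:
    """One leg's uniformly sampled tri-axial accel + gyro stream (SI units)."""

    side: str  # "left" | "right"
    time: np.ndarray  # (n,) seconds
    accel: np.ndarray  # (n, 3) m/s^2, sensor frame
    gyro: np.ndarray  # (n, 3) rad/s, sensor frame; column 2 = sagittal/pitch

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float).reshape(-1, 3)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(-1, 3)
        n = len(self.time)
        if self.accel.shape[0] != n or self.gyro.shape[0] != n:
            raise ValueError("time, accel and gyro must have equal length")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def sampling_rate(self) -> float:
        if len(self.time) < 2:
            raise ValueError("need >= 2 samples to infer a sampling rate")
        return 1.0 / float(np.median(np.diff(self.time)))

    def validate(self, spec: SensorSpec | None = None) -> list[str]:
        """Return a list of invariant violations (empty means valid)."""
        problems: list[str] = []
        n = len(self.time)
        for name, arr in (("time", self.time), ("accel", self.accel), ("gyro", self.gyro)):
            if not np.all(np.isfinite(arr)):
                row = int(np.argwhere(~np.isfinite(arr))[0][0])
                problems.append(f"non-finite value in {name} at row {row}")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                problems.append(f"time not strictly increasing at row {row}")
            else:
                step = float(np.median(dt))
                bad = np.abs(dt - step) > TIME_TOLERANCE
                if np.any(bad):
                    row = int(np.argmax(bad)) + 1
                    problems.append(
                        f"non-uniform sampling at row {row}: "
                        f"dt={dt[row - 1]:.6g}s vs step={step:.6g}s"
                    )
                if spec is not None and abs(step - 1.0 / spec.sampling_rate) > TIME_TOLERANCE:
                    problems.append(
                        f"sampling step {step:.6g}s does not match spec "
                        f"rate {spec.sampling_rate:g} Hz"
                    )
        if spec is not None and n:
            amax = np.max(np.abs(self.accel))
            if amax > spec.accel_range * (1 + 1e-9):
                row = int(np.argwhere(np.abs(self.accel) > spec.accel_range)[0][0])
                problems.append(
                    f"accel magnitude {amax:.3f} m/s^2 exceeds range "
                    f"±{spec.accel_range:.3f} m/s^2 (first at row {row})"
                )
            gmax = np.max(np.abs(self.gyro))
            if gmax > spec.gyro_range * (1 + 1e-9):
                row = int(np.argwhere(np.abs(self.gyro) > spec.gyro_range)[0][0])
                problems.append(
                    f"gyro magnitude {gmax:.3f} rad/s exceeds range "
                    f"±{spec.gyro_range:.3f} rad/s (first at row {row})"
                )
        return problems


@dataclass
class WalkSession:
    """A two-leg recording of one walking bout by one participant."""

    participant_id: str
    group: str
    left: ImuSeries
    right: ImuSeries
    spec: SensorSpec = field(default_factory=SensorSpec)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_imu_csv(series: ImuSeries, path: str | Path) -> Path:
    """Write a series in the canonical SI dialect (deterministic bytes)."""
    path = Path(path)
    data = np.column_stack([series.time, series.accel, series.gyro]) if len(series) else None
    with open(path, "w", newline="\n") as fh:
        fh.write("# units: " + ",".join(_SI_UNITS) + "\n")
        fh.write(",".join(_CSV_COLUMNS) + "\n")
        if data is not None:
            for row in data:
                fh.write(",".join(f"{v:.9f}" for v in row) + "\n")
    return path


def _parse_units(line: str) -> tuple[str, ...]:
    units = tuple(u.strip() for u in line.split(":", 1)[1].split(","))
    if len(units) != 7:
        raise ImuIoError(f"units comment must declare 7 units, got {len(units)}")
    return units


def read_imu_csv(
    path: str | Path,
    spec: SensorSpec | None = None,
    side: str | None = None,
) -> ImuSeries:
    """Read one leg's CSV, converting declared g / deg/s units to SI.

    Raises typed errors naming the first offending row for missing columns,
    non-uniform sampling, and sensor-range violations.
    """
    path = Path(path)
    units = _SI_UNITS
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# units:"):
            units = _parse_units(first)
            header = fh.readline()
        else:
            header = first
        cols = tuple(c.strip() for c in header.strip().split(","))
        if cols != _CSV_COLUMNS:
            missing = set(_CSV_COLUMNS) - set(cols)
            raise MissingColumnError(
                f"{path.name}: expected columns {_CSV_COLUMNS}, got {cols}"
                + (f" (missing {sorted(missing)})" if missing else "")
            )
        raw = np.loadtxt(fh, delimiter=",", ndmin=2) if fh else np.empty((0, 7))
    if raw.size == 0:
        raw = raw.reshape(0, 7)
    if raw.shape[1] != 7:
        raise ImuIoError(f"{path.name}: expected 7 numeric columns, got {raw.shape[1]}")

    time = raw[:, 0]
    accel = raw[:, 1:4].copy()
    gyro = raw[:, 4:7].copy()
    for j, u in enumerate(units[1:4]):
        if u in ("g", "G"):
            accel[:, j] *= GRAVITY
        elif u not in ("m/s^2", "m/s2"):
            raise ImuIoError(f"unsupported accel unit {u!r}")
    for j, u in enumerate(units[4:7]):
        if u in ("deg/s", "dps"):
            gyro[:, j] *= _DEG2RAD
        elif u != "rad/s":
            raise ImuIoError(f"unsupported gyro unit {u!r}")

    if side is None:
        stem = path.stem.lower()
        side = "right" if "right" in stem else "left"
    series = ImuSeries(side=side, time=time, accel=accel, gyro=gyro)

    if len(series) >= 2:
        dt = np.diff(series.time)
        step = float(np.median(dt))
        bad = np.abs(dt - step) > TIME_TOLERANCE
        if np.any(bad):
            row = int(np.argmax(bad)) + 1
            raise NonUniformSamplingError(
                f"{path.name}: non-uniform sampling at data row {row}", row=row
            )
    if spec is not None and len(series):
        over_a = np.abs(series.accel) > spec.accel_range * (1 + 1e-9)
        if np.any(over_a):
            row = int(np.argwhere(over_a)[0][0])
            raise RangeExceededError(
                f"{path.name}: accel exceeds ±{spec.accel_range_g:g} g at data row {row}",
                row=row,
            )
        over_g = np.abs(series.gyro) > spec.gyro_range * (1 + 1e-9)
        if np.any(over_g):
            row = int(np.argwhere(over_g)[0][0])
            raise RangeExceededError(
                f"{path.name}: gyro exceeds ±{spec.gyro_range_dps:g} deg/s at data row {row}",
                row=row,
            )
    return series


def validate_session(session: WalkSession) -> list[str]:
    """Collect every invariant violation in the session; never raises.

    Left/right clock synchronisation is assumed (a shared session clock);
    the check below only verifies overlapping time support and matching
    sampling rates, mirroring that assumption.
    """
    report: list[str] = []
    for side_name, series in (("left", session.left), ("right", session.right)):
        if series.side != side_name:
            report.append(f"{side_name} slot holds a series tagged {series.side!r}")
        report.extend(f"{side_name}: {p}" for p in series.validate(session.spec))
    if len(session.left) >= 2 and len(session.right) >= 2:
        rl = session.left.sampling_rate
        rr = session.right.sampling_rate
        if abs(rl - rr) > 1e-6 * max(rl, rr):
            report.append(f"spec mismatch: left {rl:g} Hz vs right {rr:g} Hz")
        lo = max(session.left.time[0], session.right.time[0])
        hi = min(session.left.time[-1], session.right.time[-1])
        if hi <= lo:
            report.append("left/right series have no overlapping time support")
    return report


def session_to_csv(session: WalkSession, out_dir: str | Path) -> dict[str, Path]:
    """Write ``<participant>_left.csv`` / ``_right.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for series in (session.left, session.right):
        p = out_dir / f"{session.participant_id}_{series.side}.csv"
        write_imu_csv(series, p)
        paths[series.side] = p
    return paths
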