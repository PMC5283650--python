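"""Skeletal time-series containers, I/O, clock sync and spatial registration.

Two depth cameras each track one participant's 25-joint skeleton.  This
module reads/writes those streams, shifts one camera's clock onto the
other's (the session's physical sync cue gives the offset), estimates the
rigid transform that maps one camera frame into the other from a static
calibration pose, and merges the two streams onto one uniform time grid.

Coordinate convention: right-handed, y is up (vertical); the horizontal
plane is x-z.  Positions are millimetres, time is seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "KINECT_JOINTS",
    "UPPER_BODY_JOINTS",
    "SkeletonTimeSeries",
    "RigidTransform",
    "DyadRecording",
    "read_skeleton",
    "write_skeleton",
    "apply_time_offset",
    "estimate_rigid_transform",
    "suggest_time_offset",
    "merge_dyad",
]

#: Canonical Kinect v2 joint names (25 joints).
KINECT_JOINTS: tuple[str, ...] = (
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
)

#: The 13 upper-body joints used in the analysis (head, neck, the three
#: spine joints, shoulders, elbows, wrists, and the two hip/pelvis joints).
#: Leg joints are excluded as too noisy for tracking.
UPPER_BODY_JOINTS: tuple[str, ...] = (
    "Head", "Neck", "SpineShoulder", "SpineMid", "SpineBase",
    "ShoulderLeft", "ShoulderRight",
    "ElbowLeft", "ElbowRight",
    "WristLeft", "WristRight",
    "HipLeft", "HipRight",
)


class SkeletonError(ValueError):
    """Malformed or inconsistent skeletal data."""


@dataclass(frozen=True)
class SkeletonTimeSeries:
    """One participant's joint-position trajectories with tracking flags.

    Attributes
    ----------
    participant_id : str
        Label for the participant.
    timestamps : (n,) float array
        Sample times in seconds, strictly increasing.
    joints : tuple of str
        Ordered joint names; columns of ``positions``/``tracked``.
    positions : (n, j, 3) float array
        Joint positions in mm.  Finite wherever ``tracked`` is True.
    tracked : (n, j) bool array
        Per-joint per-sample tracking flag from the sensor.
    fps_nominal : float
        Nominal frame rate in Hz (30 for Kinect v2).
    """

    participant_id: str
    timestamps: np.ndarray
    joints: tuple[str, ...]
    positions: np.ndarray
    tracked: np.ndarray
    fps_nominal: float = 30.0

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        tr = np.asarray(self.tracked, dtype=bool)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "tracked", tr)
        object.__setattr__(self, "joints", tuple(self.joints))
        if t.ndim != 1:
            raise SkeletonError("timestamps must be 1-D")
        n, j = t.shape[0], len(self.joints)
        if p.shape != (n, j, 3):
            raise SkeletonError(
                f"positions shape {p.shape} != ({n}, {j}, 3)")
        if tr.shape != (n, j):
            raise SkeletonError(f"tracked shape {tr.shape} != ({n}, {j})")
        if n > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise SkeletonError("timestamps must be strictly increasing")
            med = float(np.median(dt))
            if abs(med - 1.0 / self.fps_nominal) > 0.2 / self.fps_nominal:
                raise SkeletonError(
                    f"median sampling interval {med:.4f}s deviates >20% "
                    f"from nominal 1/{self.fps_nominal}s")
        if not np.isfinite(p[tr]).all():
            raise SkeletonError("non-finite position on a tracked sample")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def joint_index(self, name: str) -> int:
        try:
            return self.joints.index(name)
        except ValueError:
            raise KeyError(f"joint {name!r} not in series") from None

    def joint_positions(self, name: str) -> np.ndarray:
        """(n, 3) positions of a single joint."""
        return self.positions[:, self.joint_index(name), :]

    def require_joints(self, names=UPPER_BODY_JOINTS) -> None:
        missing = [j for j in names if j not in self.joints]
        if missing:
            raise SkeletonError(f"missing mandatory joints: {missing}")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform y = R x + t (rotation + translation, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation 3-vector")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError("rotation matrix must have det +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of points."""
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)


@dataclass(frozen=True)
class DyadRecording:
    """Two participants' skeletons on a shared uniform grid in one frame.

    ``rounds`` is a list of ``(label, start_s, end_s)`` conversation-round
    intervals, non-overlapping and inside the recording.
    """

    a: SkeletonTimeSeries
    b: SkeletonTimeSeries
    rounds: tuple[tuple[str, float, float], ...] = ()
    frame: str = "camera_a"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rounds",
            tuple((str(l), float(s), float(e)) for l, s, e in self.rounds))
        if not np.array_equal(self.a.timestamps, self.b.timestamps):
            raise SkeletonError("dyad members must share one time grid")
        t0, t1 = self.a.timestamps[0], self.a.timestamps[-1]
        prev_end = -np.inf
        for label, s, e in sorted(self.rounds, key=lambda r: r[1]):
            if s >= e:
                raise SkeletonError(f"round {label!r} has start >= end")
            if s < t0 - 1e-9 or e > t1 + 1e-9:
                raise SkeletonError(f"round {label!r} outside recording")
            if s < prev_end - 1e-9:
                raise SkeletonError("rounds overlap")
            prev_end = e

    @property
    def timestamps(self) -> np.ndarray:
        return self.a.timestamps

    @property
    def fps(self) -> float:
        return self.a.fps_nominal

    def round_slices(self) -> list[tuple[str, slice]]:
        """Index slices for each round (whole recording if no rounds set)."""
        t = self.timestamps
        if not self.rounds:
            return [("all", slice(0, t.shape[0]))]
        out = []
        for label, s, e in self.rounds:
            i0 = int(np.searchsorted(t, s - 1e-9, side="left"))
            i1 = int(np.searchsorted(t, e + 1e-9, side="right"))
            out.append((label, slice(i0, i1)))
        return out

    def save_dir(self, path) -> None:
        """Serialize to a directory of CSVs plus a rounds.yaml."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_skeleton(self.a, path / "a.csv")
        write_skeleton(self.b, path / "b.csv")
        meta = {
            "frame": self.frame,
            "rounds": [list(r) for r in self.rounds],
        }
        (path / "rounds.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load_dir(cls, path) -> "DyadRecording":
        path = Path(path)
        meta = yaml.safe_load((path / "rounds.yaml").read_text())
        return cls(
            a=read_skeleton(path / "a.csv"),
            b=read_skeleton(path / "b.csv"),
            rounds=tuple(tuple(r) for r in meta.get("rounds", [])),
            frame=meta.get("frame", "camera_a"),
        )


# ---------------------------------------------------------------------------
# I/O

_CSV_COLUMNS = ["time_s", "joint", "x_mm", "y_mm", "z_mm", "tracked"]


def read_skeleton(path, schema: str = "csv", *, participant_id: str | None = None,
                  fps_nominal: float = 30.0,
                  required_joints=UPPER_BODY_JOINTS) -> SkeletonTimeSeries:
    """Read a skeletal time series from long-format CSV or JSON.

    CSV schema (header required)::

        time_s,joint,x_mm,y_mm,z_mm,tracked

    with one row per (sample, joint).  The JSON schema holds the same
    content as ``{"participant_id", "fps_nominal", "timestamps", "joints",
    "positions", "tracked"}``.

    Untracked samples are preserved with their flags, never dropped.
    Raises ``SkeletonError`` naming the offending line for malformed rows
    and for missing mandatory joints.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema == "json":
        payload = json.loads(path.read_text())
        s = SkeletonTimeSeries(
            participant_id=payload.get("participant_id", path.stem),
            timestamps=np.asarray(payload["timestamps"], dtype=float),
            joints=tuple(payload["joints"]),
            positions=np.asarray(payload["positions"], dtype=float),
            tracked=np.asarray(payload["tracked"], dtype=bool),
            fps_nominal=float(payload.get("fps_nominal", fps_nominal)),
        )
        if required_joints:
            s.require_joints(required_joints)
        return s
    if schema != "csv":
        raise ValueError(f"unknown schema {schema!r}")

    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = set(_CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SkeletonError(f"{path}: missing columns {sorted(missing_cols)}")
    # validate row-wise: tracked rows must have finite coordinates
    coords = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    tracked = df["tracked"].to_numpy()
    if tracked.dtype == object:
        tracked = df["tracked"].astype(str).str.lower().isin(["1", "true", "t"]).to_numpy()
    tracked = tracked.astype(bool)
    bad = tracked & ~np.isfinite(coords).all(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # +2: header + 1-based
        raise SkeletonError(
            f"{path}: non-finite coordinate on tracked row (line {line})")

    joints_present = list(dict.fromkeys(df["joint"]))
    # canonical order where known, file order for extras
    joints = tuple(sorted(
        joints_present,
        key=lambda j: (KINECT_JOINTS.index(j) if j in KINECT_JOINTS else 99,
                       joints_present.index(j))))
    times = np.asarray(sorted(df["time_s"].unique()), dtype=float)
    n, nj = times.shape[0], len(joints)
    tidx = {t: i for i, t in enumerate(times)}
    jidx = {j: i for i, j in enumerate(joints)}
    positions = np.full((n, nj, 3), np.nan)
    tracked_arr = np.zeros((n, nj), dtype=bool)
    rows_t = df["time_s"].map(tidx).to_numpy()
    rows_j = df["joint"].map(jidx).to_numpy()
    positions[rows_t, rows_j, :] = coords
    tracked_arr[rows_t, rows_j] = tracked

    s = SkeletonTimeSeries(
        participant_id=participant_id or path.stem,
        timestamps=times, joints=joints, positions=positions,
        tracked=tracked_arr, fps_nominal=fps_nominal)
    if required_joints:
        s.require_joints(required_joints)
    return s


def write_skeleton(s: SkeletonTimeSeries, path, schema: str = "csv") -> None:
    """Write a series in the long CSV (or JSON) schema; numeric round-trip safe."""
    path = Path(path)
    if schema == "json":
        payload = {
            "participant_id": s.participant_id,
            "fps_nominal": s.fps_nominal,
            "timestamps": s.timestamps.tolist(),
            "joints": list(s.joints),
            "positions": s.positions.tolist(),
            "tracked": s.tracked.astype(int).tolist(),
        }
        path.write_text(json.dumps(payload))
        return
    n, nj = s.n_samples, len(s.joints)
    df = pd.DataFrame({
        "time_s": np.repeat(s.timestamps, nj),
        "joint": np.tile(np.asarray(s.joints, dtype=object), n),
        "x_mm": s.positions[:, :, 0].ravel(),
        "y_mm": s.positions[:, :, 1].ravel(),
        "z_mm": s.positions[:, :, 2].ravel(),
        "tracked": s.tracked.astype(int).ravel(),
    })
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Time synchronization

def apply_time_offset(s: SkeletonTimeSeries, offset: float) -> SkeletonTimeSeries:
    """Shift all timestamps by ``offset`` seconds; data untouched."""
    if not np.isfinite(offset):
        raise ValueError("offset must be finite")
    return replace(s, timestamps=s.timestamps + float(offset))


def suggest_time_offset(a: SkeletonTimeSeries, b: SkeletonTimeSeries,
                        joint: str = "WristRight",
                        max_lag_s: float = 30.0) -> float:
    """Suggest the clock offset of ``b`` relative to ``a``.

    Locates the global peak of the cross-correlation of the two wrist
    speeds (the sync cue is a mutual high-five, a sharp simultaneous wrist
    movement).  Returns the offset (in seconds) to *add* to ``b``'s clock.
    Heuristic helper only; the pipeline takes the offset as user input.
    """
    from scipy.signal import correlate, correlation_lags

    def wrist_speed(s: SkeletonTimeSeries) -> np.ndarray:
        p = s.joint_positions(joint)
        v = np.gradient(p, s.timestamps, axis=0)
        return np.linalg.norm(v, axis=1)

    sa, sb = wrist_speed(a), wrist_speed(b)
    sa = sa - sa.mean()
    sb = sb - sb.mean()
    n = min(sa.shape[0], sb.shape[0])
    sa, sb = sa[:n], sb[:n]
    c = correlate(sa, sb, mode="full")
    lags = correlation_lags(n, n, mode="full")
    dt = 1.0 / a.fps_nominal
    keep = np.abs(lags * dt) <= max_lag_s
    best = lags[keep][np.argmax(c[keep])]
    # b lags a by `best` samples: add best*dt to b's clock
    return float(best * dt + (a.timestamps[0] - b.timestamps[0]))


# ---------------------------------------------------------------------------
# Space calibration (Kabsch least-squares rigid registration)

def estimate_rigid_transform(pts_src: np.ndarray,
                             pts_dst: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``pts_src`` onto ``pts_dst``.

    Closed-form Kabsch solution on N >= 3 non-collinear corresponding
    points (in calibration use, the same joints of one static body seen by
    both cameras, time-averaged over the static excerpt).  No scaling.
    The residual RMS distance after alignment is stored on the result.
    """
    src = np.asarray(pts_src, dtype=float)
    dst = np.asarray(pts_dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    n = src.shape[0]
    if n < 3:
        raise ValueError("need at least 3 corresponding points")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    x, y = src - cs, dst - cd
    # collinearity check: second singular value of the centered cloud
    sv = np.linalg.svd(x, compute_uv=False)
    if sv[1] < max(1e-9, 1e-9 * sv[0]):
        raise ValueError("degenerate (collinear) point configuration")
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cd - r @ cs
    resid = dst - (src @ r.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return RigidTransform(r, t, residual_rms=rms)


# ---------------------------------------------------------------------------
# Merging the two streams

def transform_skeleton(s: SkeletonTimeSeries, t: RigidTransform) -> SkeletonTimeSeries:
    """Apply a rigid transform to every joint position."""
    return replace(s, positions=t.apply(s.positions))


def _resample(s: SkeletonTimeSeries, grid: np.ndarray) -> SkeletonTimeSeries:
    """Linear resampling onto ``grid``.

    A resampled point is flagged tracked only if both bracketing input
    samples were tracked, so sensor gaps survive resampling.
    """
    t = s.timestamps
    n, nj = grid.shape[0], len(s.joints)
    pos = np.empty((n, nj, 3))
    for j in range(nj):
        for k in range(3):
            pos[:, j, k] = np.interp(grid, t, s.positions[:, j, k])
    lo = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, t.shape[0] - 1)
    hi = np.clip(lo + 1, 0, t.shape[0] - 1)
    exact = np.isclose(grid, t[lo])
    hi = np.where(exact, lo, hi)
    tracked = s.tracked[lo, :] & s.tracked[hi, :]
    # interpolation across an untracked bracketing sample can produce NaN;
    # those points are untracked by construction, keep them finite-safe
    return replace(s, timestamps=grid, positions=pos, tracked=tracked)


def merge_dyad(a: SkeletonTimeSeries, b: SkeletonTimeSeries,
               t_b: RigidTransform | None = None,
               grid_fps: float = 30.0,
               rounds=()) -> DyadRecording:
    """Place ``b`` in ``a``'s frame and resample both onto one uniform grid.

    Only the temporal overlap of the two (already offset-corrected) streams
    is retained.  Raises on empty overlap.
    """
    if t_b is not None:
        b = transform_skeleton(b, t_b)
    t0 = max(a.timestamps[0], b.timestamps[0])
    t1 = min(a.timestamps[-1], b.timestamps[-1])
    if t1 <= t0:
        raise SkeletonError("no temporal overlap between the two streams")
    dt = 1.0 / grid_fps
    n = int(np.floor((t1 - t0) / dt)) + 1
    grid = t0 + dt * np.arange(n)
    ra = _resample(a, grid)
    rb = _resample(b, grid)
    rounds = tuple((l, max(float(s), t0), min(float(e), grid[-1]))
                   for l, s, e in rounds)
    return DyadRecording(a=ra, b=rb, rounds=rounds, frame="camera_a")
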