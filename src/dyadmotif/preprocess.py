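"""Tracking-error repair, smoothing, differentiation and speed normalization.

Depth-camera skeletal tracking is noisy: most frames have at least one
imperfectly tracked upper-body joint, and tracking faults show up as
discontinuous position spikes or frozen values.  The cleaning chain is
fixed: short untracked gaps are linearly interpolated, discontinuous
outliers removed with a 5-point trimmed mean, the result smoothed with
three passes of a 5-point running median, and only then differentiated to
velocities.  A 3 Hz boxcar low-pass is provided for visualization but is
never part of the analysis chain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .skeldata import SkeletonTimeSeries, UPPER_BODY_JOINTS

__all__ = [
    "JointVelocitySeries",
    "interpolate_missing",
    "despike",
    "median_smooth",
    "lowpass_3hz",
    "differentiate",
    "smooth_skeleton",
    "zscore_joint_speeds",
]


@dataclass(frozen=True)
class JointVelocitySeries:
    """Per-joint 3-D velocities and scalar speeds on the common grid.

    ``speed[i, j] = sqrt(vx^2 + vy^2 + vz^2)`` of joint ``j`` at sample
    ``i`` (mm/s).  ``valid`` marks samples whose position survived gap
    repair (untracked runs longer than the gap limit stay invalid and are
    excluded from downstream windows that touch them).
    """

    timestamps: np.ndarray
    joints: tuple[str, ...]
    velocities: np.ndarray  # (n, j, 3) mm/s
    speed: np.ndarray       # (n, j) mm/s
    valid: np.ndarray       # (n, j) bool
    fps: float

    def joint_index(self, name: str) -> int:
        return self.joints.index(name)

    def joint_velocity(self, name: str) -> np.ndarray:
        return self.velocities[:, self.joint_index(name), :]


def interpolate_missing(s: SkeletonTimeSeries, max_gap: float = 0.5) -> SkeletonTimeSeries:
    """Linearly interpolate untracked runs of duration <= ``max_gap`` seconds.

    Every coordinate is made finite (long gaps and edge gaps are filled by
    linear interpolation / edge-hold too, so smoothing never meets NaN),
    but only gaps <= ``max_gap`` are re-flagged tracked; longer runs stay
    flagged untracked and are excluded from any window that touches them.
    """
    pos = s.positions.copy()
    tracked = s.tracked.copy()
    n = s.n_samples
    idx = np.arange(n)
    for j in range(len(s.joints)):
        good = s.tracked[:, j]
        if good.all():
            continue
        if not good.any():
            pos[:, :, :][:, j, :] = 0.0
            continue
        for k in range(3):
            pos[:, j, k] = np.interp(idx, idx[good], s.positions[good, j, k])
        # re-flag short gaps as usable
        bad = ~good
        starts = np.flatnonzero(bad & ~np.roll(bad, 1))
        if bad[0]:
            starts = np.unique(np.concatenate([[0], starts]))
        for st in starts:
            en = st
            while en < n and bad[en]:
                en += 1
            gap_s = (s.timestamps[min(en, n - 1)] - s.timestamps[max(st - 1, 0)])
            interior = st > 0 and en < n
            if interior and gap_s <= max_gap:
                tracked[st:en, j] = True
    return replace(s, positions=pos, tracked=tracked)


def _check_1d(x: np.ndarray, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if x.shape[0] < min_len:
        raise ValueError(f"series shorter than {min_len} samples")
    return x


def despike(x: np.ndarray) -> np.ndarray:
    """Remove discontinuous outliers with a sliding 5-point trimmed mean.

    Each output sample is the mean of the three middle order statistics of
    the centred 5-sample window (the extreme min and max are dropped).
    Edge samples use the shrunken centred window with the same trim rule
    while at least 3 points remain, else the plain mean.
    """
    x = _check_1d(x, 5)
    n = x.shape[0]
    out = np.empty_like(x)
    w = sliding_window_view(x, 5)
    out[2:n - 2] = (w.sum(axis=1) - w.max(axis=1) - w.min(axis=1)) / 3.0
    for i in (0, 1, n - 2, n - 1):
        lo, hi = max(0, i - 2), min(n, i + 3)
        win = x[lo:hi]
        if win.shape[0] >= 3:
            out[i] = (win.sum() - win.max() - win.min()) / (win.shape[0] - 2)
        else:  # pragma: no cover - unreachable for n >= 5
            out[i] = win.mean()
    return out


def median_smooth(x: np.ndarray, passes: int = 3, window: int = 5) -> np.ndarray:
    """``passes`` consecutive runs of a ``window``-point running median.

    Edge policy: median of the samples available in the centred window.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be odd and >= 3")
    x = _check_1d(x, window)
    n = x.shape[0]
    half = window // 2
    for _ in range(passes):
        out = np.empty_like(x)
        out[half:n - half] = np.median(sliding_window_view(x, window), axis=1)
        for i in range(half):
            out[i] = np.median(x[:i + half + 1])
            out[n - 1 - i] = np.median(x[n - 1 - i - half:])
        x = out
    return x


def lowpass_3hz(x: np.ndarray, fs: float = 30.0, cutoff: float = 3.0) -> np.ndarray:
    """Square-pulse (boxcar moving-average) low-pass at ``cutoff`` Hz.

    Width = round(fs / cutoff) samples.  Exposed for visualization only;
    no analysis operation calls it.
    """
    from scipy.ndimage import uniform_filter1d

    x = np.asarray(x, dtype=float)
    width = max(1, int(round(fs / cutoff)))
    return uniform_filter1d(x, size=width, mode="nearest")


def _smooth_positions(positions: np.ndarray) -> np.ndarray:
    """despike + 3x median-5, vectorised over (n, j, 3)."""
    n = positions.shape[0]
    flat = positions.reshape(n, -1)
    out = np.empty_like(flat)
    # despike, all columns at once
    w = sliding_window_view(flat, 5, axis=0)
    out[2:n - 2] = (w.sum(axis=-1) - w.max(axis=-1) - w.min(axis=-1)) / 3.0
    for i in (0, 1, n - 2, n - 1):
        lo, hi = max(0, i - 2), min(n, i + 3)
        win = flat[lo:hi]
        out[i] = (win.sum(axis=0) - win.max(axis=0) - win.min(axis=0)) / (hi - lo - 2)
    # 3 passes of median-5
    x = out
    for _ in range(3):
        nxt = np.empty_like(x)
        nxt[2:n - 2] = np.median(sliding_window_view(x, 5, axis=0), axis=-1)
        for i in range(2):
            nxt[i] = np.median(x[:i + 3], axis=0)
            nxt[n - 1 - i] = np.median(x[n - 3 - i:], axis=0)
        x = nxt
    return x.reshape(positions.shape)


def smooth_skeleton(s: SkeletonTimeSeries, max_gap: float = 0.5) -> SkeletonTimeSeries:
    """Full position-cleaning chain: gap repair -> despike -> 3x median-5.

    Smoothing operates on positions only; timestamps and sample count are
    preserved exactly.  Velocity is derived afterwards and never
    re-smoothed.
    """
    s = interpolate_missing(s, max_gap=max_gap)
    return replace(s, positions=_smooth_positions(s.positions))


def differentiate(s: SkeletonTimeSeries) -> JointVelocitySeries:
    """Differentiate smoothed positions to velocities and speeds.

    Central differences in the interior, one-sided at the edges.  The
    speed of a joint is the root of the sum of its three squared velocity
    components.
    """
    t = s.timestamps
    dt = np.median(np.diff(t))
    v = np.gradient(s.positions, dt, axis=0)
    speed = np.sqrt(np.sum(v ** 2, axis=2))
    # a velocity sample is valid only if the position samples entering the
    # difference stencil are tracked
    tr = s.tracked
    valid = tr.copy()
    valid[1:-1] &= tr[:-2] & tr[2:]
    if valid.shape[0] >= 2:
        valid[0] &= tr[1]
        valid[-1] &= tr[-2]
    return JointVelocitySeries(
        timestamps=t, joints=s.joints, velocities=v, speed=speed,
        valid=valid, fps=s.fps_nominal)


def preprocess(s: SkeletonTimeSeries, max_gap: float = 0.5) -> JointVelocitySeries:
    """Convenience: smooth_skeleton then differentiate."""
    return differentiate(smooth_skeleton(s, max_gap=max_gap))


def zscore_joint_speeds(v: JointVelocitySeries,
                        joints=UPPER_BODY_JOINTS) -> np.ndarray:
    """Normalize each joint's speed to mean 0, SD 1 over the full span.

    Returns an (n_samples, n_joints) matrix in the order of ``joints``.
    The normalization span is the whole series handed in (for the study
    design: the concatenated three rounds).  A zero-variance joint raises,
    naming the joint.
    """
    cols = []
    for name in joints:
        sp = v.speed[:, v.joint_index(name)]
        sd = sp.std()
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"joint {name!r} has zero speed variance; "
                             "cannot normalize")
        cols.append((sp - sp.mean()) / sd)
    return np.column_stack(cols)
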