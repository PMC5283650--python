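"""Still / solo / co-active window classification from torso speed.

The torso speed of each participant is summarised in sliding 2-second
windows by its RMS, then compared with a per-participant, per-round
activity threshold: 15% of the larger of (i) that participant's maximum
speed in the round and (ii) the maximum speed over all participants in
the whole dataset.  A window is *still* when both participants are below
threshold, *solo* when exactly one is above, and *co-active* when both
are.  Solo windows are sub-classified parallel vs perpendicular by
comparing the in-window RMS of the mover's two velocity components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .torso import TorsoVelocitySeries

__all__ = [
    "WindowGrid",
    "ActivityThresholds",
    "WindowActivity",
    "window_grid",
    "window_rms",
    "compute_thresholds",
    "classify_windows",
    "activity_fractions",
    "CLASS_LABELS",
]

CLASS_LABELS = ("still", "solo_a", "solo_b", "coactive")
STILL, SOLO_A, SOLO_B, COACTIVE = range(4)


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window layout over a sample range.

    ``starts`` are window start indices; each window spans
    ``[start, start + window)`` samples and is labelled at its centre.
    """

    starts: np.ndarray
    window: int
    stride: int
    fps: float
    t0: float = 0.0

    @property
    def n_windows(self) -> int:
        return self.starts.shape[0]

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.window // 2

    @property
    def center_times(self) -> np.ndarray:
        return self.t0 + self.centers / self.fps

    @property
    def window_s(self) -> float:
        return self.window / self.fps

    @property
    def stride_s(self) -> float:
        return self.stride / self.fps


def window_grid(n_samples: int, fps: float, window_s: float = 2.0,
                stride: int | None = None, t0: float = 0.0) -> WindowGrid:
    """Build the sliding-window grid for a series of ``n_samples``.

    ``stride`` is in samples; ``None`` means non-overlapping windows
    (stride = window), the layout used for mode counting so that window
    statistics stay near-independent.  ``stride=1`` gives the dense
    timeline used for display and run-length measurement.
    """
    window = int(round(window_s * fps))
    if n_samples < window:
        raise ValueError("series shorter than one window")
    if stride is None:
        stride = window
    starts = np.arange(0, n_samples - window + 1, stride)
    return WindowGrid(starts=starts, window=window, stride=int(stride),
                      fps=fps, t0=t0)


def _window_mean_sq(x: np.ndarray, grid: WindowGrid) -> np.ndarray:
    csum = np.concatenate([[0.0], np.cumsum(np.asarray(x, float) ** 2)])
    return (csum[grid.starts + grid.window] - csum[grid.starts]) / grid.window


def window_rms(x: np.ndarray, grid: WindowGrid,
               valid: np.ndarray | None = None):
    """Centred RMS of ``x`` per window; windows touching invalid samples
    (long tracking gaps) are flagged invalid.

    Returns ``(rms, window_valid)``.
    """
    rms = np.sqrt(_window_mean_sq(x, grid))
    if valid is None:
        wvalid = np.ones(grid.n_windows, dtype=bool)
    else:
        bad = np.concatenate([[0.0], np.cumsum(~np.asarray(valid, bool))])
        wvalid = (bad[grid.starts + grid.window] - bad[grid.starts]) == 0
    return rms, wvalid


@dataclass(frozen=True)
class ActivityThresholds:
    """Per participant-round activity thresholds and their provenance.

    ``threshold(p, r) = frac * max(round_max[p, r], global_max)`` with
    ``frac = 0.15``: the larger of 15% of the participant's own maximum
    speed in the round and 15% of the dataset-wide maximum speed.
    """

    round_max: dict
    global_max: float
    frac: float = 0.15

    def threshold(self, participant: str, round_label: str) -> float:
        key = (participant, round_label)
        if key not in self.round_max:
            raise KeyError(f"no threshold for {key}")
        return self.frac * max(self.round_max[key], self.global_max)


def compute_thresholds(round_speeds: dict, frac: float = 0.15) -> ActivityThresholds:
    """Thresholds from smoothed torso speeds of every participant-round.

    ``round_speeds`` maps ``(participant, round_label)`` to that round's
    com-speed samples (invalid samples already removed).  With a single
    dyad, the dataset-wide maximum degenerates to the maximum over its two
    participants.
    """
    round_max = {}
    for key, speed in round_speeds.items():
        speed = np.asarray(speed, dtype=float)
        if speed.size == 0:
            raise ValueError(f"empty round for {key}")
        round_max[key] = float(np.max(speed))
    return ActivityThresholds(round_max=round_max,
                              global_max=max(round_max.values()), frac=frac)


@dataclass(frozen=True)
class WindowActivity:
    """Window-level activity classes for one analysed round."""

    grid: WindowGrid
    rms_a: np.ndarray
    rms_b: np.ndarray
    classes: np.ndarray    # ints, see CLASS_LABELS
    solo_dir: np.ndarray   # "parallel" | "perpendicular" | "n/a"
    valid: np.ndarray

    def class_labels(self) -> np.ndarray:
        return np.asarray(CLASS_LABELS, dtype=object)[self.classes]


def classify_windows(torso_a: TorsoVelocitySeries, torso_b: TorsoVelocitySeries,
                     grid: WindowGrid, thr_a: float, thr_b: float) -> WindowActivity:
    """Classify every window as still / solo_a / solo_b / co-active.

    Solo windows get a parallel-vs-perpendicular direction by comparing
    the mover's in-window RMS of the two components; ties break to
    parallel (deterministic, documented).
    """
    rms_a, va = window_rms(torso_a.com_speed, grid, torso_a.valid)
    rms_b, vb = window_rms(torso_b.com_speed, grid, torso_b.valid)
    valid = va & vb
    above_a = rms_a >= thr_a
    above_b = rms_b >= thr_b
    classes = np.full(grid.n_windows, STILL, dtype=int)
    classes[above_a & ~above_b] = SOLO_A
    classes[~above_a & above_b] = SOLO_B
    classes[above_a & above_b] = COACTIVE

    par_a = np.sqrt(_window_mean_sq(torso_a.v_par, grid))
    perp_a = np.sqrt(_window_mean_sq(torso_a.v_perp, grid))
    par_b = np.sqrt(_window_mean_sq(torso_b.v_par, grid))
    perp_b = np.sqrt(_window_mean_sq(torso_b.v_perp, grid))
    solo_dir = np.full(grid.n_windows, "n/a", dtype=object)
    is_a = classes == SOLO_A
    is_b = classes == SOLO_B
    solo_dir[is_a] = np.where(par_a[is_a] >= perp_a[is_a],
                              "parallel", "perpendicular")
    solo_dir[is_b] = np.where(par_b[is_b] >= perp_b[is_b],
                              "parallel", "perpendicular")
    return WindowActivity(grid=grid, rms_a=rms_a, rms_b=rms_b,
                          classes=classes, solo_dir=solo_dir, valid=valid)


def activity_fractions(wa: WindowActivity) -> dict:
    """Fraction of valid windows in each activity class (sums to 1)."""
    n = int(wa.valid.sum())
    if n == 0:
        raise ValueError("no valid windows")
    cls = wa.classes[wa.valid]
    return {label: float(np.mean(cls == i))
            for i, label in enumerate(CLASS_LABELS)}
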