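"""Motion motifs: mode over-representation against cyclic-shift surrogates.

A motion motif is a dyadic mode that occurs in the real recording far
more often than expected from the two individuals' own motion statistics.
The null is built by cyclically rotating one participant's torso time
series by at least one minute — breaking interpersonal correlation while
preserving each person's marginal sample multiset exactly — and rerunning
the windowed mode analysis on M such shifted pairs.  Per mode,
``Z = (real count - surrogate mean) / surrogate SD``; modes with
``Z > 3.1`` are motifs and ``Z < -3.1`` anti-motifs (3.1 corresponds to a
one-sided Gaussian tail below 0.001, guarding the 8 simultaneous tests).

Activity thresholds depend only on marginal maximum speeds, which cyclic
shifting preserves, so they are computed once on the real data and reused
for every surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .dyad_modes import MODE_LABELS, count_labels, mode_timeline, window_modes
from .segmentation import COACTIVE, classify_windows, window_grid
from .torso import TorsoVelocitySeries

__all__ = [
    "SurrogateEnsemble",
    "MotifReport",
    "cyclic_shift",
    "shift_torso",
    "pair_mode_counts",
    "surrogate_counts",
    "motif_zscores",
    "gaussian_tail",
]

Z_THRESHOLD = 3.1


def cyclic_shift(x: np.ndarray, offset_samples: int) -> np.ndarray:
    """Rotate a series in time; length and sample multiset are preserved.

    ``offset_samples`` must satisfy ``0 <= offset < len(x)`` (an offset
    equal to the duration would be a full wrap, i.e. no surrogate at all).
    """
    x = np.asarray(x)
    n = x.shape[0]
    if not 0 <= offset_samples < n:
        raise ValueError(f"offset {offset_samples} outside [0, {n})")
    return np.roll(x, offset_samples, axis=0)


def shift_torso(t: TorsoVelocitySeries, offset_samples: int) -> TorsoVelocitySeries:
    """Cyclically shift every channel of a torso series (validity included)."""
    return replace(
        t,
        v_par=cyclic_shift(t.v_par, offset_samples),
        v_perp=cyclic_shift(t.v_perp, offset_samples),
        v_tang=cyclic_shift(t.v_tang, offset_samples),
        com_speed=cyclic_shift(t.com_speed, offset_samples),
        valid=cyclic_shift(t.valid, offset_samples),
    )


def pair_mode_counts(torso_a: TorsoVelocitySeries, torso_b: TorsoVelocitySeries,
                     thr_a: float, thr_b: float,
                     window_s: float = 2.0,
                     stride: int | None = None) -> dict[str, int]:
    """Windowed mode analysis of one torso pair -> per-label counts.

    Counts are tallied over non-overlapping windows by default so that
    the surrogate count distributions stay near-independent.
    """
    grid = window_grid(torso_a.n_samples, torso_a.fps, window_s, stride)
    wa = classify_windows(torso_a, torso_b, grid, thr_a, thr_b)
    analyse = wa.valid & (wa.classes == COACTIVE)
    modes = window_modes(torso_a, torso_b, grid, which=analyse)
    labels = mode_timeline(wa, modes)
    return count_labels(labels)


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Cyclic-shift surrogate ensemble: offsets and per-surrogate counts."""

    offsets_s: np.ndarray
    counts: tuple[dict[str, int], ...]
    seed: int
    min_shift_s: float

    @property
    def m(self) -> int:
        return len(self.counts)

    def count_matrix(self) -> np.ndarray:
        """(M, 8) matrix of per-mode counts in MODE_LABELS order."""
        return np.array([[c[m] for m in MODE_LABELS] for c in self.counts],
                        dtype=float)


def surrogate_counts(torso_a: TorsoVelocitySeries, torso_b: TorsoVelocitySeries,
                     thr_a: float, thr_b: float,
                     m: int = 30, seed: int = 0,
                     min_shift_s: float = 60.0,
                     window_s: float = 2.0,
                     stride: int | None = None) -> SurrogateEnsemble:
    """Mode counts on ``m`` cyclically shifted copies of the pair.

    Participant b's series is shifted, a's untouched.  Offsets are drawn
    uniformly from ``[min_shift_s, duration - min_shift_s]`` with a
    recorded seed, keeping every surrogate at least one minute away from
    the real alignment in either direction.  Requires a recording longer
    than ``2 * min_shift_s``.
    """
    fps = torso_b.fps
    duration = torso_b.n_samples / fps
    if duration <= 2 * min_shift_s:
        raise ValueError(
            f"recording ({duration:.0f}s) too short for cyclic shifts of "
            f">= {min_shift_s:.0f}s on both sides")
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(min_shift_s, duration - min_shift_s, size=m)
    counts = []
    for off in offsets:
        shifted = shift_torso(torso_b, int(round(off * fps)))
        counts.append(pair_mode_counts(torso_a, shifted, thr_a, thr_b,
                                       window_s=window_s, stride=stride))
    return SurrogateEnsemble(offsets_s=offsets, counts=tuple(counts),
                             seed=seed, min_shift_s=min_shift_s)


@dataclass(frozen=True)
class MotifReport:
    """Per-mode occurrence statistics and motif / anti-motif calls."""

    real: dict[str, int]
    surrogate_mean: dict[str, float]
    surrogate_sd: dict[str, float]
    z: dict[str, float]
    calls: dict[str, str]  # "motif" | "anti-motif" | "none"
    z_threshold: float = Z_THRESHOLD

    def motif_labels(self) -> list[str]:
        return [m for m, c in self.calls.items() if c == "motif"]

    def anti_motif_labels(self) -> list[str]:
        return [m for m, c in self.calls.items() if c == "anti-motif"]

    def to_dict(self) -> dict:
        return {m: {"real": self.real[m],
                    "surrogate_mean": self.surrogate_mean[m],
                    "surrogate_sd": self.surrogate_sd[m],
                    "z": self.z[m],
                    "call": self.calls[m]}
                for m in MODE_LABELS}


def motif_zscores(real: dict[str, int], ensemble: SurrogateEnsemble,
                  z_threshold: float = Z_THRESHOLD) -> MotifReport:
    """Z-score each mode's real count against the surrogate ensemble.

    ``SD = 0`` with the real count at the surrogate mean gives ``Z = 0``;
    ``SD = 0`` with a different real count gives a signed infinite Z,
    called by its sign.
    """
    mat = ensemble.count_matrix()
    means = mat.mean(axis=0)
    sds = mat.std(axis=0)
    z, calls, meand, sdd = {}, {}, {}, {}
    for i, mode in enumerate(MODE_LABELS):
        diff = real[mode] - means[i]
        if sds[i] > 0:
            zi = diff / sds[i]
        else:
            zi = 0.0 if diff == 0 else np.copysign(np.inf, diff)
        z[mode] = float(zi)
        meand[mode] = float(means[i])
        sdd[mode] = float(sds[i])
        if zi > z_threshold:
            calls[mode] = "motif"
        elif zi < -z_threshold:
            calls[mode] = "anti-motif"
        else:
            calls[mode] = "none"
    return MotifReport(real=dict(real), surrogate_mean=meand,
                       surrogate_sd=sdd, z=z, calls=calls,
                       z_threshold=z_threshold)


def gaussian_tail(z: float) -> float:
    """One-sided upper-tail probability of the standard normal at ``z``."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(norm.sf(z))
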