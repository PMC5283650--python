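"""Dyadic motion modes: windowed PCA of the 6-coordinate torso system.

Within each 2-second window the dyad's torso motion is described by six
velocity coordinates — (v_par, v_perp, v_tang) for each person.  The
first principal component of the within-window covariance is the window's
*motion mode*.  Co-active modes are classified to idealized *pure modes*
(parallel/perpendicular sway, in sync or anti-phase, or mixed) by
projecting the mode's four non-tangential loadings onto unit-norm
templates; solo and still labels come from the activity segmentation, not
from this classifier.

Eight labels cover the dyadic repertoire: the five co-active pure modes
plus solo-parallel, solo-perpendicular (either party pooled) and mutual
stillness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import (COACTIVE, SOLO_A, SOLO_B, STILL, WindowActivity,
                           WindowGrid)
from .torso import TorsoVelocitySeries

__all__ = [
    "MODE_LABELS",
    "PURE_MODE_TEMPLATES",
    "ModeVector",
    "WindowModes",
    "window_mode",
    "window_modes",
    "classify_pure_mode",
    "mode_timeline",
    "count_labels",
    "run_lengths",
    "cross_correlation",
    "correlation_time",
]

_S = 1.0 / np.sqrt(2.0)

#: Unit-norm pure-mode templates over (par_a, perp_a, par_b, perp_b).
#: ``mixed`` (one person parallel, the other perpendicular) carries both
#: orderings and is scored by the better of the two.
PURE_MODE_TEMPLATES: dict[str, tuple[np.ndarray, ...]] = {
    "par_sync": (np.array([_S, 0.0, _S, 0.0]),),
    "par_anti": (np.array([_S, 0.0, -_S, 0.0]),),
    "perp_sync": (np.array([0.0, _S, 0.0, _S]),),
    "perp_anti": (np.array([0.0, _S, 0.0, -_S]),),
    "mixed": (np.array([_S, 0.0, 0.0, _S]), np.array([0.0, _S, _S, 0.0])),
}

#: Deterministic classification (and tie-break) order for the 5 co-active
#: pure modes, followed by the segmentation-assigned labels.
COACTIVE_LABELS = ("par_sync", "par_anti", "perp_sync", "perp_anti", "mixed")
MODE_LABELS = COACTIVE_LABELS + ("solo_par", "solo_perp", "both_still")


@dataclass(frozen=True)
class ModeVector:
    """One window's first-PC loading over the 6 torso coordinates."""

    loadings: np.ndarray       # (6,), unit norm
    explained_var: float       # fraction in [0, 1]
    center_time: float

    def __post_init__(self) -> None:
        l = np.asarray(self.loadings, dtype=float)
        object.__setattr__(self, "loadings", l)
        if l.shape != (6,):
            raise ValueError("mode loadings must be a 6-vector")
        if abs(np.linalg.norm(l) - 1.0) > 1e-10:
            raise ValueError("mode loadings must be unit norm")
        if not 0.0 <= self.explained_var <= 1.0 + 1e-12:
            raise ValueError("explained variance must be in [0, 1]")


def _stack_coords(torso_a: TorsoVelocitySeries,
                  torso_b: TorsoVelocitySeries) -> np.ndarray:
    return np.column_stack([torso_a.v_par, torso_a.v_perp, torso_a.v_tang,
                            torso_b.v_par, torso_b.v_perp, torso_b.v_tang])


def window_mode(window_data: np.ndarray,
                center_time: float = 0.0,
                min_samples: int = 10) -> ModeVector | None:
    """First PC of one window's (samples x 6) torso-velocity block.

    Returns ``None`` for degenerate (zero-variance) windows, which are
    excluded downstream.
    """
    x = np.asarray(window_data, dtype=float)
    if x.ndim != 2 or x.shape[1] != 6:
        raise ValueError("window data must be (samples, 6)")
    if x.shape[0] < min_samples:
        raise ValueError(f"window needs >= {min_samples} valid samples")
    x = x - x.mean(axis=0)
    cov = (x.T @ x) / (x.shape[0] - 1)
    total = np.trace(cov)
    if total <= 0:
        return None
    evals, evecs = np.linalg.eigh(cov)
    lead = evecs[:, -1]
    k = int(np.argmax(np.abs(lead)))
    if lead[k] < 0:
        lead = -lead
    return ModeVector(loadings=lead, explained_var=float(evals[-1] / total),
                      center_time=float(center_time))


@dataclass(frozen=True)
class WindowModes:
    """Per-window mode loadings over a grid (NaN rows where not computed)."""

    grid: WindowGrid
    loadings: np.ndarray       # (n_windows, 6)
    explained_var: np.ndarray  # (n_windows,), NaN where not computed
    computed: np.ndarray       # bool


def window_modes(torso_a: TorsoVelocitySeries, torso_b: TorsoVelocitySeries,
                 grid: WindowGrid,
                 which: np.ndarray | None = None) -> WindowModes:
    """Batch first-PC extraction for the selected windows of a grid.

    ``which`` masks the windows to analyse (e.g. the valid non-still
    ones); all eigendecompositions run batched.
    """
    coords = _stack_coords(torso_a, torso_b)
    nw = grid.n_windows
    if which is None:
        which = np.ones(nw, dtype=bool)
    loadings = np.full((nw, 6), np.nan)
    ev = np.full(nw, np.nan)
    computed = np.zeros(nw, dtype=bool)
    idx = np.flatnonzero(which)
    if idx.size == 0:
        return WindowModes(grid, loadings, ev, computed)
    w = grid.window
    blocks = np.stack([coords[s:s + w] for s in grid.starts[idx]])
    blocks = blocks - blocks.mean(axis=1, keepdims=True)
    covs = np.einsum("nwi,nwj->nij", blocks, blocks) / (w - 1)
    totals = np.trace(covs, axis1=1, axis2=2)
    ok = totals > 0
    evals, evecs = np.linalg.eigh(covs[ok])
    lead = evecs[:, :, -1]
    # deterministic sign: largest-|entry| positive
    kmax = np.argmax(np.abs(lead), axis=1)
    signs = np.sign(lead[np.arange(lead.shape[0]), kmax])
    lead = lead * signs[:, None]
    sel = idx[ok]
    loadings[sel] = lead
    ev[sel] = evals[:, -1] / totals[ok]
    computed[sel] = True
    return WindowModes(grid, loadings, ev, computed)


def classify_pure_mode(mode) -> tuple[str, float]:
    """Classify a co-active motion mode to the best-matching pure mode.

    The tangential loadings are dropped (small contribution to overall
    speed), the remaining 4-vector (par_a, perp_a, par_b, perp_b) is
    renormalized, and the score for each pure mode is the absolute dot
    product with its template (the absolute value absorbs the PC sign
    ambiguity; ``mixed`` takes the better of its two orderings).  The
    label is the first maximal score in the fixed order
    par_sync < par_anti < perp_sync < perp_anti < mixed.

    Returns ``("unclassifiable", 0.0)`` when all loading sits in the
    tangential coordinates.
    """
    l6 = mode.loadings if isinstance(mode, ModeVector) else np.asarray(mode, float)
    vec = np.array([l6[0], l6[1], l6[3], l6[4]])
    norm = np.linalg.norm(vec)
    if norm == 0:
        return "unclassifiable", 0.0
    vec = vec / norm
    best_label, best_score = "unclassifiable", -1.0
    for label in COACTIVE_LABELS:
        score = max(abs(float(t @ vec)) for t in PURE_MODE_TEMPLATES[label])
        if score > best_score:
            best_label, best_score = label, score
    return best_label, best_score


def mode_timeline(wa: WindowActivity, modes: WindowModes) -> np.ndarray:
    """Eight-way label per window centre.

    Still and solo labels come from the activity segmentation (solo of
    either party pooled by direction); co-active windows take the
    pure-mode classifier's label.  Invalid or degenerate windows are
    labelled ``"invalid"``.
    """
    nw = wa.grid.n_windows
    labels = np.full(nw, "invalid", dtype=object)
    for i in range(nw):
        if not wa.valid[i]:
            continue
        c = wa.classes[i]
        if c == STILL:
            labels[i] = "both_still"
        elif c in (SOLO_A, SOLO_B):
            labels[i] = ("solo_par" if wa.solo_dir[i] == "parallel"
                         else "solo_perp")
        elif c == COACTIVE:
            if modes.computed[i]:
                labels[i], _ = classify_pure_mode(modes.loadings[i])
            # degenerate windows stay "invalid"
    return labels


def count_labels(labels: np.ndarray) -> dict[str, int]:
    """Occurrence count of each of the 8 mode labels (invalid excluded)."""
    return {m: int(np.sum(labels == m)) for m in MODE_LABELS}


def run_lengths(labels: np.ndarray, stride_s: float, label: str):
    """Durations (seconds) of maximal consecutive runs of ``label``.

    Returns ``(durations, mean)``; the mean is ``None`` when the label
    never occurs.
    """
    mask = np.asarray(labels == label)
    if not mask.any():
        return [], None
    padded = np.concatenate([[False], mask, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    durations = [(e - s) * stride_s for s, e in zip(starts, ends)]
    return durations, float(np.mean(durations))


def cross_correlation(speed_a: np.ndarray, speed_b: np.ndarray,
                      fps: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-covariance of two speed series at all lags.

    Returns ``(lags_s, c)`` where ``c`` is the correlation coefficient at
    each lag (positive lag: a trails b).  Raises on zero-variance input.
    """
    from scipy.signal import correlate, correlation_lags

    a = np.asarray(speed_a, dtype=float)
    b = np.asarray(speed_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("speeds must be 1-D and equal length")
    a = a - a.mean()
    b = b - b.mean()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance speed series")
    n = a.shape[0]
    c = correlate(a, b, mode="full") / (n * sa * sb)
    lags = correlation_lags(n, n, mode="full") / fps
    return lags, c


def correlation_time(speed_a: np.ndarray, speed_b: np.ndarray,
                     fps: float) -> float:
    """Width (seconds) of the central cross-correlation lobe.

    Normalized cross-covariance of the two (mean-removed) speeds; the
    correlation time is the full width of the contiguous lag interval
    around the peak where the correlation exceeds 1/e of its peak value.
    """
    _, c = cross_correlation(speed_a, speed_b, fps)
    peak = int(np.argmax(c))
    level = c[peak] / np.e
    lo = peak
    while lo > 0 and c[lo - 1] > level:
        lo -= 1
    hi = peak
    while hi < c.shape[0] - 1 and c[hi + 1] > level:
        hi += 1
    return (hi - lo + 1) / fps
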