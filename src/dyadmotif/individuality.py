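"""Dyad individuality: mode-distribution histograms and their distances.

Each analysed round yields a cloud of window modes; projecting every
(non-still) window's first-PC loadings onto the two *parallel*
coordinates — (par_a, par_b) — gives a 2-D distribution characteristic
of the dyad.  Principal components are sign-ambiguous, so each point is
flipped into the upper half plane (par_b >= 0) before binning.  Dyads
show individuality when their own histograms from different rounds are
closer to each other (RMS of bin-wise differences) than to other dyads',
testable with a two-sample Kolmogorov-Smirnov test on the intra- vs
inter-dyad distance samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp

__all__ = [
    "ModeHistogram",
    "parallel_histogram",
    "histogram_distance",
    "intra_inter_distances",
    "ks_two_sample",
]


@dataclass(frozen=True)
class ModeHistogram:
    """Normalized 2-D mass over the (par_a, par_b) loading plane."""

    mass: np.ndarray       # (bins, bins), sums to 1
    edges: np.ndarray      # shared bin edges over [-1, 1]
    n_windows: int

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", m)
        if abs(m.sum() - 1.0) > 1e-12:
            raise ValueError("histogram mass must sum to 1")

    @property
    def bins(self) -> int:
        return self.mass.shape[0]


def _upper_half_plane(par_a: np.ndarray, par_b: np.ndarray):
    """Resolve PC sign: flip both loadings so that par_b >= 0.

    On the boundary (par_b == 0) the point is flipped so that par_a >= 0,
    making the rule deterministic.
    """
    flip = (par_b < 0) | ((par_b == 0) & (par_a < 0))
    sign = np.where(flip, -1.0, 1.0)
    return par_a * sign, par_b * sign


def parallel_histogram(loadings: np.ndarray, bins: int = 25) -> ModeHistogram:
    """Histogram of window modes over the two parallel loadings.

    ``loadings`` is an (n_windows, 6) array of first-PC loadings from
    non-still windows (co-active and solo; still windows are discarded
    upstream); columns 0 and 3 are the two parallel components.  Signs
    are flipped pairwise into the upper half plane before binning.
    """
    l = np.asarray(loadings, dtype=float)
    if l.ndim != 2 or l.shape[1] not in (2, 6):
        raise ValueError("need (n, 6) mode loadings or (n, 2) parallel pairs")
    if l.shape[0] == 0:
        raise ValueError("no windows to histogram")
    if l.shape[1] == 6:
        par_a, par_b = l[:, 0], l[:, 3]
    else:
        par_a, par_b = l[:, 0], l[:, 1]
    par_a, par_b = _upper_half_plane(par_a, par_b)
    edges = np.linspace(-1.0, 1.0, bins + 1)
    h, _, _ = np.histogram2d(par_a, par_b, bins=[edges, edges])
    n = l.shape[0]
    return ModeHistogram(mass=h / h.sum(), edges=edges, n_windows=n)


def histogram_distance(h1: ModeHistogram, h2: ModeHistogram) -> float:
    """RMS of bin-wise differences between two equally binned histograms."""
    if h1.mass.shape != h2.mass.shape or not np.array_equal(h1.edges, h2.edges):
        raise ValueError("histograms must share one binning")
    return float(np.sqrt(np.mean((h1.mass - h2.mass) ** 2)))


def intra_inter_distances(histograms: dict) -> tuple[np.ndarray, np.ndarray]:
    """Split all pairwise histogram distances into intra- and inter-dyad.

    ``histograms`` maps ``(dyad_id, round_id)`` to a ``ModeHistogram``.
    Intra = all within-dyad cross-round pairs; inter = all cross-dyad
    pairs (any rounds); no pair counted twice.  Requires at least two
    dyads with at least two rounds each.
    """
    keys = sorted(histograms)
    dyads = {d for d, _ in keys}
    if len(dyads) < 2 or any(
            sum(1 for d, _ in keys if d == dy) < 2 for dy in dyads):
        raise ValueError("need >= 2 dyads with >= 2 rounds each")
    intra, inter = [], []
    for (k1, k2) in itertools.combinations(keys, 2):
        d = histogram_distance(histograms[k1], histograms[k2])
        (intra if k1[0] == k2[0] else inter).append(d)
    return np.asarray(intra), np.asarray(inter)


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: (D, asymptotic p-value).

    ``D`` is the supremum distance between the two empirical CDFs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    res = ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
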