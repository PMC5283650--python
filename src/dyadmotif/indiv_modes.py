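"""Individual motion modes: PCA of joint speeds with shuffle significance.

Each participant's motion is summarised by principal components of the
z-scored speeds of the 13 upper-body joints.  Component significance is
judged against a null ensemble in which every joint's speed series is
independently permuted in time (destroying inter-joint and temporal
structure while preserving each joint's speed distribution): a component
is significant when its real explained variance exceeds the shuffled mean
by more than three shuffled standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PCAResult",
    "SignificanceCall",
    "pca",
    "shuffle_significance",
    "loading_similarity",
]


@dataclass(frozen=True)
class PCAResult:
    """Loadings (rows, unit norm) and explained-variance fractions."""

    loadings: np.ndarray        # (n_components, n_features)
    explained_var: np.ndarray   # fractions, non-increasing, sum 1
    n_samples: int

    def __post_init__(self) -> None:
        ev = np.asarray(self.explained_var, dtype=float)
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("explained variances must be non-increasing")
        if abs(ev.sum() - 1.0) > 1e-8:
            raise ValueError("explained variances must sum to 1")


@dataclass(frozen=True)
class SignificanceCall:
    """Per-component real EV vs shuffled-null EV and the 3-SD flags."""

    real_ev: np.ndarray
    shuffled_mean: np.ndarray
    shuffled_sd: np.ndarray
    significant: np.ndarray
    n_shuffles: int
    seed: int


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-|entry| of each component made positive."""
    out = loadings.copy()
    for i, row in enumerate(out):
        k = int(np.argmax(np.abs(row)))
        if row[k] < 0:
            out[i] = -row
    return out


def pca(x: np.ndarray, standardize: bool = True) -> PCAResult:
    """PCA via eigendecomposition of the sample covariance.

    Columns are centred (and, by default, scaled to unit SD — the joint
    speeds enter the analysis z-scored).  Loadings are orthonormal rows
    sorted by decreasing eigenvalue with a deterministic sign convention.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 samples and >=2 features")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("zero-variance feature; cannot standardize")
        x = x / sd
    cov = (x.T @ x) / (x.shape[0] - 1)
    total = np.trace(cov)
    if total <= 0:
        raise ValueError("degenerate input: zero total variance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    loadings = _fix_signs(evecs[:, order].T)
    return PCAResult(loadings=loadings, explained_var=evals / evals.sum(),
                     n_samples=x.shape[0])


def shuffle_significance(x: np.ndarray, n_shuffles: int = 1000,
                         rng_seed: int = 0,
                         n_sd: float = 3.0) -> SignificanceCall:
    """Shuffle-null significance of PCA components.

    For each shuffle every column (joint speed series) is permuted in time
    independently of the others and the PCA explained variances are
    recomputed.  Component ``i`` is flagged significant when
    ``real_ev[i] > mean_shuffled_ev[i] + n_sd * sd_shuffled_ev[i]``.
    """
    x = np.asarray(x, dtype=float)
    real = pca(x).explained_var
    rng = np.random.default_rng(rng_seed)
    evs = np.empty((n_shuffles, x.shape[1]))
    for s in range(n_shuffles):
        shuffled = rng.permuted(x, axis=0)
        evs[s] = pca(shuffled).explained_var
    mean, sd = evs.mean(axis=0), evs.std(axis=0)
    return SignificanceCall(
        real_ev=real, shuffled_mean=mean, shuffled_sd=sd,
        significant=real > mean + n_sd * sd,
        n_shuffles=n_shuffles, seed=rng_seed)


def loading_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Squared Pearson correlation between two loading vectors.

    Loadings are sign-ambiguous; squaring the correlation makes the
    measure invariant to a global sign flip of either vector.  Raises on
    zero-variance input.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("loading vectors must be 1-D and equal length")
    du, dv = u - u.mean(), v - v.mean()
    su, sv = np.linalg.norm(du), np.linalg.norm(dv)
    if su == 0 or sv == 0:
        raise ValueError("zero-variance loading vector")
    r = float(du @ dv / (su * sv))
    return r * r
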