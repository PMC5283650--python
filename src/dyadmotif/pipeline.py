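"""End-to-end orchestration: recording -> modes -> motifs -> report.

``run_all`` chains the stages on one dyadic recording with a single
config and seed: position cleaning and differentiation, torso
decomposition, activity thresholds and window classification per round,
windowed dyadic PCA and pure-mode labelling, cyclic-shift surrogate
motif statistics, and summary diagnostics.  The serialized config is
embedded in the report so a rerun with identical inputs is bit-identical
for the deterministic stages and reproducible for the seeded ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np

from . import indiv_modes as im
from .dyad_modes import (MODE_LABELS, WindowModes, correlation_time,
                         count_labels, mode_timeline, run_lengths,
                         window_modes)
from .motifs import MotifReport, motif_zscores, surrogate_counts
from .preprocess import differentiate, smooth_skeleton, zscore_joint_speeds
from .segmentation import (STILL, ActivityThresholds, WindowActivity,
                           activity_fractions, classify_windows,
                           compute_thresholds, window_grid)
from .skeldata import DyadRecording, UPPER_BODY_JOINTS
from .torso import TorsoVelocitySeries, torso_velocities

__all__ = ["PipelineConfig", "RoundAnalysis", "DyadAnalysis", "run_all",
           "analyze_recording"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with their standard defaults."""

    window_s: float = 2.0
    max_gap_s: float = 0.5
    threshold_frac: float = 0.15
    n_shuffles: int = 1000
    n_surrogates: int = 30
    min_shift_s: float = 60.0
    z_threshold: float = 3.1
    hist_bins: int = 25
    seed: int = 0
    #: run the (slower) individual-PCA shuffle analysis in run_all
    include_individual_pca: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _slice_torso(t: TorsoVelocitySeries, sl: slice) -> TorsoVelocitySeries:
    return replace(t, timestamps=t.timestamps[sl], v_par=t.v_par[sl],
                   v_perp=t.v_perp[sl], v_tang=t.v_tang[sl],
                   com_speed=t.com_speed[sl], valid=t.valid[sl])


@dataclass(frozen=True)
class RoundAnalysis:
    """Windowed analysis of one conversation round."""

    label: str
    activity: WindowActivity
    modes: WindowModes
    timeline: np.ndarray
    counts: dict[str, int]


@dataclass(frozen=True)
class DyadAnalysis:
    """Everything computed for one recording."""

    torso_a: TorsoVelocitySeries
    torso_b: TorsoVelocitySeries
    thresholds: ActivityThresholds
    rounds: tuple[RoundAnalysis, ...]
    motifs: MotifReport | None

    def total_counts(self) -> dict[str, int]:
        return {m: sum(r.counts[m] for r in self.rounds) for m in MODE_LABELS}

    def nonstill_loadings(self) -> np.ndarray:
        """Mode loadings of all valid non-still windows (for histograms)."""
        rows = []
        for r in self.rounds:
            keep = r.modes.computed
            rows.append(r.modes.loadings[keep])
        return np.vstack(rows) if rows else np.empty((0, 6))


def analyze_round(torso_a: TorsoVelocitySeries, torso_b: TorsoVelocitySeries,
                  thr_a: float, thr_b: float, label: str = "all",
                  window_s: float = 2.0,
                  stride: int | None = None) -> RoundAnalysis:
    """Window classification + dyadic modes + 8-way timeline for one round.

    Modes are extracted for every valid moving (non-still) window so the
    parallel-loading histograms can include solo windows; the pure-mode
    classifier labels only the co-active ones.
    """
    grid = window_grid(torso_a.n_samples, torso_a.fps, window_s, stride)
    wa = classify_windows(torso_a, torso_b, grid, thr_a, thr_b)
    moving = wa.valid & (wa.classes != STILL)
    modes = window_modes(torso_a, torso_b, grid, which=moving)
    timeline = mode_timeline(wa, modes)
    return RoundAnalysis(label=label, activity=wa, modes=modes,
                         timeline=timeline, counts=count_labels(timeline))


def analyze_recording(rec: DyadRecording,
                      cfg: PipelineConfig = PipelineConfig(),
                      with_motifs: bool = True) -> DyadAnalysis:
    """Preprocess, decompose and window-analyse a recording.

    Thresholds follow the 15% rule per participant-round with the global
    maximum taken over both participants and all rounds of this
    recording.  Motif Z-scores compare per-round counts summed over
    rounds against cyclic-shift surrogates sharing one offset per
    surrogate index.
    """
    sm_a = smooth_skeleton(rec.a, max_gap=cfg.max_gap_s)
    sm_b = smooth_skeleton(rec.b, max_gap=cfg.max_gap_s)
    torso_a = torso_velocities(sm_a, differentiate(sm_a))
    torso_b = torso_velocities(sm_b, differentiate(sm_b))

    slices = rec.round_slices()
    round_speeds = {}
    for label, sl in slices:
        for pid, torso in (("a", torso_a), ("b", torso_b)):
            sp = torso.com_speed[sl][torso.valid[sl]]
            round_speeds[(pid, label)] = sp
    thresholds = compute_thresholds(round_speeds, frac=cfg.threshold_frac)

    rounds = []
    for label, sl in slices:
        rounds.append(analyze_round(
            _slice_torso(torso_a, sl), _slice_torso(torso_b, sl),
            thresholds.threshold("a", label), thresholds.threshold("b", label),
            label=label, window_s=cfg.window_s))
    analysis = DyadAnalysis(torso_a=torso_a, torso_b=torso_b,
                            thresholds=thresholds, rounds=tuple(rounds),
                            motifs=None)
    if not with_motifs:
        return analysis

    # surrogate ensembles per round, counts summed across rounds per
    # surrogate index; thresholds are shift-invariant and reused
    ensembles = []
    for (label, sl), ra in zip(slices, rounds):
        ensembles.append(surrogate_counts(
            _slice_torso(torso_a, sl), _slice_torso(torso_b, sl),
            thresholds.threshold("a", label), thresholds.threshold("b", label),
            m=cfg.n_surrogates, seed=cfg.seed, min_shift_s=cfg.min_shift_s,
            window_s=cfg.window_s))
    summed = ensembles[0]
    if len(ensembles) > 1:
        counts = tuple(
            {m: sum(e.counts[i][m] for e in ensembles) for m in MODE_LABELS}
            for i in range(cfg.n_surrogates))
        summed = replace(summed, counts=counts)
    report = motif_zscores(analysis.total_counts(), summed,
                           z_threshold=cfg.z_threshold)
    return replace(analysis, motifs=report)


def _individual_pca_report(rec: DyadRecording, cfg: PipelineConfig) -> dict:
    out = {}
    for pid, skel in (("a", rec.a), ("b", rec.b)):
        sm = smooth_skeleton(skel, max_gap=cfg.max_gap_s)
        vel = differentiate(sm)
        x = zscore_joint_speeds(vel, UPPER_BODY_JOINTS)
        call = im.shuffle_significance(x, n_shuffles=cfg.n_shuffles,
                                       rng_seed=cfg.seed)
        out[pid] = {
            "explained_var": [float(v) for v in call.real_ev],
            "significant": [bool(f) for f in call.significant],
            "n_shuffles": call.n_shuffles,
        }
    return out


def run_all(rec: DyadRecording,
            cfg: PipelineConfig = PipelineConfig()) -> dict:
    """Full pipeline on one recording -> JSON-serializable report."""
    analysis = analyze_recording(rec, cfg, with_motifs=True)
    counts = analysis.total_counts()
    fracs = [activity_fractions(r.activity) for r in analysis.rounds]
    n_valid = [int(r.activity.valid.sum()) for r in analysis.rounds]
    tot = sum(n_valid)
    fractions = {k: sum(f[k] * n for f, n in zip(fracs, n_valid)) / tot
                 for k in fracs[0]}

    # dense timeline for run-length diagnostics on the first round
    label0, sl0 = rec.round_slices()[0]
    dense = analyze_round(
        _slice_torso(analysis.torso_a, sl0), _slice_torso(analysis.torso_b, sl0),
        analysis.thresholds.threshold("a", label0),
        analysis.thresholds.threshold("b", label0),
        label=label0, window_s=cfg.window_s, stride=1)
    stride_s = dense.activity.grid.stride_s
    _, mean_sync_run = run_lengths(dense.timeline, stride_s, "par_sync")

    report = {
        "config": cfg.to_dict(),
        "activity_fractions": fractions,
        "mode_counts": counts,
        "motifs": analysis.motifs.to_dict(),
        "motif_calls": analysis.motifs.motif_labels(),
        "anti_motif_calls": analysis.motifs.anti_motif_labels(),
        "diagnostics": {
            "correlation_time_s": float(correlation_time(
                analysis.torso_a.com_speed, analysis.torso_b.com_speed,
                analysis.torso_a.fps)),
            "mean_par_sync_run_s": (None if mean_sync_run is None
                                    else float(mean_sync_run)),
        },
    }
    if cfg.include_individual_pca:
        report["individual_pca"] = _individual_pca_report(rec, cfg)
    return report
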