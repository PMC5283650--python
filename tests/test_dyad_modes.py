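"""Windowed dyadic PCA, pure-mode classification and timeline diagnostics."""

import numpy as np
import pytest
import scipy.linalg

from dyadmotif.dyad_modes import (MODE_LABELS, PURE_MODE_TEMPLATES,
                                  classify_pure_mode, correlation_time,
                                  count_labels, cross_correlation,
                                  mode_timeline, run_lengths, window_mode,
                                  window_modes)
from dyadmotif.segmentation import classify_windows, window_grid
from test_segmentation import make_torso

S = 1 / np.sqrt(2)


def sinusoid_window(n=60, fps=30.0, phase=0.0):
    t = np.arange(n) / fps
    return np.sin(2 * np.pi * 0.5 * t + phase)


class TestWindowMode:
    def test_parallel_sync_rank1(self):
        sig = sinusoid_window()
        x = np.zeros((60, 6))
        x[:, 0] = sig   # v_par_a
        x[:, 3] = sig   # v_par_b
        m = window_mode(x)
        assert m.explained_var == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(m.loadings),
                                   [S, 0, 0, S, 0, 0], atol=1e-10)
        assert np.sign(m.loadings[0]) == np.sign(m.loadings[3])

    def test_parallel_anti_rank1(self):
        sig = sinusoid_window()
        x = np.zeros((60, 6))
        x[:, 0] = sig
        x[:, 3] = -sig
        m = window_mode(x)
        np.testing.assert_allclose(np.abs(m.loadings),
                                   [S, 0, 0, S, 0, 0], atol=1e-10)
        assert np.sign(m.loadings[0]) == -np.sign(m.loadings[3])

    def test_matches_bruteforce_eigendecomposition(self, rng):
        """First PC equals the leading eigenvector of np.cov computed with
        scipy's independent eigensolver, to 1e-8."""
        for _ in range(10):
            x = rng.normal(size=(60, 6)) @ rng.normal(size=(6, 6))
            m = window_mode(x)
            cov = np.cov(x.T)
            evals, evecs = scipy.linalg.eigh(cov)
            np.testing.assert_allclose(np.abs(m.loadings),
                                       np.abs(evecs[:, -1]), atol=1e-8)
            assert m.explained_var == pytest.approx(
                evals[-1] / evals.sum(), abs=1e-10)

    def test_degenerate_window_is_none(self):
        assert window_mode(np.zeros((60, 6))) is None

    def test_min_samples_enforced(self):
        with pytest.raises(ValueError, match="valid samples"):
            window_mode(np.zeros((5, 6)))

    def test_batch_matches_single(self, rng):
        ta = make_torso(rng.normal(size=300) * 10, rng.normal(size=300) * 5)
        tb = make_torso(rng.normal(size=300) * 8, rng.normal(size=300) * 6)
        g = window_grid(300, 30.0, 2.0)
        wm = window_modes(ta, tb, g)
        coords = np.column_stack([ta.v_par, ta.v_perp, ta.v_tang,
                                  tb.v_par, tb.v_perp, tb.v_tang])
        for i, s in enumerate(g.starts):
            single = window_mode(coords[s:s + g.window])
            np.testing.assert_allclose(wm.loadings[i], single.loadings,
                                       atol=1e-10)
            assert wm.explained_var[i] == pytest.approx(single.explained_var)


class TestClassifyPureMode:
    @pytest.mark.parametrize("label", list(PURE_MODE_TEMPLATES))
    def test_templates_classify_to_themselves_exactly(self, label):
        for tmpl in PURE_MODE_TEMPLATES[label]:
            l6 = np.array([tmpl[0], tmpl[1], 0.0, tmpl[2], tmpl[3], 0.0])
            got, score = classify_pure_mode(l6)
            assert got == label
            assert score == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("label", list(PURE_MODE_TEMPLATES))
    def test_global_sign_flip_invariance(self, label):
        for tmpl in PURE_MODE_TEMPLATES[label]:
            l6 = np.array([tmpl[0], tmpl[1], 0.0, tmpl[2], tmpl[3], 0.0])
            assert classify_pure_mode(-l6) == classify_pure_mode(l6)

    def test_random_modes_sign_invariant(self, rng):
        for _ in range(50):
            l6 = rng.normal(size=6)
            l6 /= np.linalg.norm(l6)
            assert classify_pure_mode(l6)[0] == classify_pure_mode(-l6)[0]

    def test_tie_break_order(self):
        """loadings all on par_a tie par_sync/par_anti/mixed at 1/sqrt(2);
        the fixed order resolves to par_sync.  Verified against scores
        enumerated by hand."""
        l6 = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        scores = {lab: max(abs(t @ np.array([1.0, 0, 0, 0]))
                           for t in PURE_MODE_TEMPLATES[lab])
                  for lab in PURE_MODE_TEMPLATES}
        assert scores["par_sync"] == scores["par_anti"] == pytest.approx(S)
        label, score = classify_pure_mode(l6)
        assert label == "par_sync"
        assert score == pytest.approx(S)

    def test_tangential_only_unclassifiable(self):
        l6 = np.array([0.0, 0.0, S, 0.0, 0.0, S])
        assert classify_pure_mode(l6) == ("unclassifiable", 0.0)

    def test_tangential_dropped_before_scoring(self):
        """Loading leaking into tangential coordinates does not change the
        label once the 4-vector is renormalized."""
        base = np.array([S, 0.0, 0.0, S, 0.0, 0.0])
        leaky = np.array([0.5, 0.0, 0.5, 0.5, 0.0, 0.5])
        assert classify_pure_mode(leaky)[0] == classify_pure_mode(base)[0]


class TestTimeline:
    def test_all_still_recording(self):
        ta = make_torso(np.zeros(300))
        g = window_grid(300, 30.0, 2.0)
        wa = classify_windows(ta, ta, g, 1.0, 1.0)
        modes = window_modes(ta, ta, g, which=np.zeros(g.n_windows, bool))
        labels = mode_timeline(wa, modes)
        assert (labels == "both_still").all()

    def test_labels_cover_every_valid_window(self, planted_analysis):
        for ra in planted_analysis.rounds:
            valid = ra.activity.valid
            assert np.isin(ra.timeline[valid],
                           list(MODE_LABELS) + ["invalid"]).all()
            # every valid co-active window with a computed mode got a label
            assert not np.any((ra.timeline == "invalid") & valid
                              & ra.modes.computed)

    def test_planted_modes_recovered(self, planted_dyad, planted_analysis):
        """>=90% of windows lying fully inside a scheduled block are
        labelled with the planted mode."""
        _, _, truth = planted_dyad
        ra = planted_analysis.rounds[0]
        times = ra.activity.grid.center_times
        ws = ra.activity.grid.window_s
        hits = total = 0
        for i, t in enumerate(times):
            expected = truth.expected_label(t, ws)
            if expected is None or ra.timeline[i] == "invalid":
                continue
            total += 1
            hits += ra.timeline[i] == expected
        assert total > 20
        assert hits / total >= 0.9

    def test_explained_variance_at_least_one_sixth(self, planted_analysis):
        """PC1 of 6 coordinates can never fall below the average share."""
        for ra in planted_analysis.rounds:
            ev = ra.modes.explained_var[ra.modes.computed]
            assert (ev >= 1 / 6 - 1e-12).all()


class TestRunLengths:
    def test_single_run(self):
        labels = np.array(["x"] * 30, dtype=object)
        durations, mean = run_lengths(labels, 0.1, "x")
        assert durations == [pytest.approx(3.0)]
        assert mean == pytest.approx(3.0)

    def test_alternating_runs_of_one_stride(self):
        labels = np.array(["x", "y"] * 10, dtype=object)
        durations, mean = run_lengths(labels, 0.5, "x")
        assert len(durations) == 10
        assert all(d == pytest.approx(0.5) for d in durations)

    def test_absent_label(self):
        durations, mean = run_lengths(np.array(["a", "b"], object), 1.0, "z")
        assert durations == [] and mean is None

    def test_planted_runs_recovered(self):
        labels = np.array(["s"] * 5 + ["x"] * 20 + ["s"] * 7 + ["x"] * 12
                          + ["s"] * 4, dtype=object)
        durations, _ = run_lengths(labels, 1 / 30, "x")
        np.testing.assert_allclose(durations, [20 / 30, 12 / 30])


class TestCorrelationTime:
    def test_gaussian_pulse_closed_form(self):
        """The autocorrelation of a Gaussian pulse of width sigma is a
        Gaussian of width sigma*sqrt(2); its 1/e full width is 4*sigma."""
        fps, sigma = 30.0, 1.0
        t = np.arange(-90, 90, 1 / fps)
        x = np.exp(-t ** 2 / (2 * sigma ** 2))
        width = correlation_time(x, x, fps)
        assert width == pytest.approx(4 * sigma, rel=0.05)

    def test_white_noise_delta_correlation(self, rng):
        a = rng.normal(size=3000)
        b = rng.normal(size=3000)
        width = correlation_time(a, a, 30.0)
        assert width <= 3 / 30.0

    def test_shifted_copy_peaks_at_lag(self, rng):
        fps = 30.0
        a = np.convolve(rng.normal(size=2000), np.ones(15) / 15, mode="same")
        k = 45
        b = np.roll(a, -k)
        lags, c = cross_correlation(a, b, fps)
        assert lags[np.argmax(c)] == pytest.approx(k / fps, abs=2 / fps)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_time(np.ones(100), np.ones(100), 30.0)


def test_count_labels_counts_all_eight():
    labels = np.array(["par_sync"] * 3 + ["both_still"] * 2 + ["invalid"],
                      dtype=object)
    counts = count_labels(labels)
    assert set(counts) == set(MODE_LABELS)
    assert counts["par_sync"] == 3
    assert counts["both_still"] == 2
    assert sum(counts.values()) == 5  # invalid excluded
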