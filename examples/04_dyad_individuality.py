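"""Dyad individuality from parallel-mode distributions.

Simulates three dyads with different motion-mode mixtures, three rounds
each, histograms each round's window modes over the two parallel
loadings, and compares within-dyad to between-dyad histogram distances
(RMS of bin-wise differences) with a two-sample KS test.  Dyads with
distinct mixtures are closer to their own rounds than to other dyads.
"""

from dyadmotif import (PipelineConfig, SynthConfig, intra_inter_distances,
                       ks_two_sample, parallel_histogram, simulate_dyad)
from dyadmotif.pipeline import analyze_recording

styles = {
    "swayers": dict(p_still=0.2, p_par=0.6, p_perp=0.2, coupling=0.8),
    "stillest": dict(p_still=0.5, p_par=0.2, p_perp=0.3, coupling=0.0),
    "sidesteppers": dict(p_still=0.1, p_par=0.3, p_perp=0.6, coupling=0.3),
}

histograms = {}
for d, (name, style) in enumerate(styles.items()):
    for r in range(3):
        cfg = SynthConfig(duration_s=120.0, seed=0, **style)
        rec, _ = simulate_dyad(cfg, seed=d * 10 + r)
        analysis = analyze_recording(rec, PipelineConfig(),
                                     with_motifs=False)
        histograms[(name, r)] = parallel_histogram(
            analysis.nonstill_loadings(), bins=25)

intra, inter = intra_inter_distances(histograms)
d_stat, p = ks_two_sample(intra, inter)
print(f"mean intra-dyad distance: {intra.mean():.4f} ({intra.size} pairs)")
print(f"mean inter-dyad distance: {inter.mean():.4f} ({inter.size} pairs)")
print(f"KS test: D = {d_stat:.2f}, p = {p:.2g}")
# A small intra mean with D near 1 and p << 0.05 says each dyad's mode
# distribution is a reproducible signature across rounds.
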