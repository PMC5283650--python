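# dyadmotif

Reduced-dimensionality analysis of two-person body motion: from
skeletal joint time series (e.g. two depth cameras, 25 joints, 30 fps)
to **dyadic motion modes** and **motion motifs** — coordinated movement
patterns that a conversing pair uses more often than the two
individuals' own motion statistics can explain.

Natural conversation involves tens of 3D coordinates per person.  The
package reduces this in three steps:

1. **Individual modes.**  PCA of the z-scored speeds of 13 upper-body
   joints; significance against 1000 per-joint temporal shuffles
   (a component is significant when its explained variance exceeds the
   shuffled mean by > 3 shuffled SDs).  Body motion in conversation is
   dominated by a rigid-torso component, so the pipeline then tracks
   each torso by its two pelvis joints, decomposed per sample into
   v<sub>∥</sub> (along the person's own hip axis — side-to-side sway),
   v<sub>⊥</sub> (fore-aft) and v<sub>tang</sub> (twist) in the
   horizontal plane.

2. **Dyadic modes.**  Sliding 2 s windows of the 6-coordinate system
   (v<sub>∥</sub>, v<sub>⊥</sub>, v<sub>tang</sub> per person).  Windows
   are *still*, *solo* or *co-active* via an RMS-speed threshold (15% of
   the larger of the participant-round maximum and the dataset maximum).
   Each co-active window's first principal component is its *motion
   mode*, classified to the nearest *pure mode* template
   (parallel/perpendicular × sync/anti, or mixed) by the score
   |p̄<sub>m</sub> · ℓ̂| over the normalized non-tangential loadings ℓ̂.

3. **Motion motifs.**  A null ensemble of M = 30 surrogates cyclically
   rotates one participant's series by ≥ 60 s, preserving each person's
   marginal statistics while breaking interpersonal alignment.  Per
   mode, Z = (real count − surrogate mean)/surrogate SD; Z > 3.1
   (Gaussian tail < 0.001, guarding 8 simultaneous tests) calls a
   motif, Z < −3.1 an anti-motif.

It also quantifies **dyad individuality**: 2-D histograms of the two
parallel loadings per round, compared by the RMS of bin-wise
differences, with a two-sample Kolmogorov–Smirnov test of within- vs
between-dyad distances.

A synthetic-data module generates two-person recordings with scheduled
sway/stillness blocks, controllable phase-locked coupling, sensor noise
and tracking dropouts — with exact ground truth, so every stage is
testable without any recording hardware.

## Worked example

Simulate four minutes of a strongly coupled dyad (every co-active block
is phase-locked parallel sway) and ask which modes are motifs
(`examples/01_detect_motifs.py`):

```python
from dyadmotif import PipelineConfig, SynthConfig, run_all, simulate_dyad

cfg = SynthConfig(duration_s=240.0, coupling=1.0, seed=42)
recording, truth = simulate_dyad(cfg)
report = run_all(recording, PipelineConfig(seed=0))
```

Output:

```
mode        real  surr mean       Z  call
par_sync      45       18.7    9.66  motif
par_anti       3       20.7   -4.67  anti-motif
perp_sync      0        1.3   -1.17  none
perp_anti     0         1.6   -1.30  none
mixed          3        5.4   -1.19  none
solo_par      21       30.3   -2.32  none
solo_perp     10        3.8    2.92  none
both_still     6        4.8    0.58  none
motifs: ['par_sync']
```

Synchronized parallel sway occurs in 45 non-overlapping 2 s windows but
only ~19 ± 2.7 in the shift surrogates: 9.7 surrogate SDs above chance,
a motion motif.  Anti-phase parallel windows are correspondingly
*under*-represented (the phase-locking converts would-be anti-phase
alignments into in-phase ones), an anti-motif.  With `coupling=0` the
two simulated participants are fully independent and no mode should be
called (the false-call rate across seeds is a few percent, the expected
tail of estimating the surrogate mean and SD from 30 draws).

The other examples each exercise one capability: individual-mode PCA
with shuffle significance (`02`), pure-mode classification of
constructed windows (`03`), dyad individuality across simulated rounds
(`04`), and two-camera ingestion with rigid calibration and clock sync
(`05`).  A thin CLI wraps the pipeline:

```bash
dyadmotif synth --seed 3 --out dyad/
dyadmotif run --in dyad/ --seed 1 --out report.json
dyadmotif ingest --a A.csv --b B.csv --calib-a CA.csv --calib-b CB.csv \
    --offset-b 1.23 --rounds rounds.yaml --out rec/
```

Skeleton files are long-format CSV
(`time_s,joint,x_mm,y_mm,z_mm,tracked`) or an equivalent JSON.

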