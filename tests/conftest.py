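import numpy as np
import pytest

from dyadmotif import SynthConfig, simulate_dyad
from dyadmotif.pipeline import PipelineConfig, analyze_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_dyad():
    """A 240 s fully coupled dyad (every co-active block phase-locked
    parallel sway) with its ground truth: the standard planted-effect
    input for recovery tests."""
    cfg = SynthConfig(duration_s=240.0, coupling=1.0, seed=7)
    rec, truth = simulate_dyad(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def planted_analysis(planted_dyad):
    """Full pipeline analysis (with motifs) of the planted dyad."""
    _, rec, _ = planted_dyad
    return analyze_recording(rec, PipelineConfig(seed=0), with_motifs=True)


@pytest.fixture(scope="session")
def null_dyad():
    """A 240 s pair of independently simulated participants."""
    cfg = SynthConfig(duration_s=240.0, coupling=0.0, seed=11)
    rec, truth = simulate_dyad(cfg)
    return cfg, rec, truth
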