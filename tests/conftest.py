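"""Shared fixtures: toy layout and session-scoped simulations."""

import numpy as np
import pytest

from replichrom import default_layout, repli
from replichrom.simulate import SimConfig, simulate_repliseq


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def repli_sim(layout):
    """Default two-cell-type Repli-seq simulation with ground truth."""
    cfg = SimConfig(seed=101)
    tracks, truth = simulate_repliseq(cfg, layout)
    return cfg, tracks, truth


@pytest.fixture(scope="session")
def timing_tracks(layout, repli_sim):
    """Window tables and timing tracks for both simulated cell types."""
    _, tracks, _ = repli_sim
    windows = {}
    timings = {}
    for ct, fc in tracks.items():
        scaled = repli.normalize_fractions(fc, layout)
        wt = repli.window_observations(scaled)
        windows[ct] = wt
        timings[ct] = repli.timing_track(wt)
    return windows, timings


@pytest.fixture(scope="session")
def chic_sim(layout):
    """30x phased-nucleosome simulation on chr4 with gene models."""
    from replichrom.simulate import simulate_chic, simulate_genes

    cfg = SimConfig(seed=202)
    cfg.chic.coverage = 30.0
    genes = simulate_genes(cfg, layout)
    samples, truth = simulate_chic(cfg, layout, chroms=["chr4"], genes=genes)
    return cfg, samples, truth, genes
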