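"""Shared fixtures: desk-scale geometry, extractor and simulated cohorts."""

import numpy as np
import pytest

from epiprs.extract import SyntheticExtractor
from epiprs.simulate import SimConfig, simulate_dataset
from epiprs.windows import WindowConfig


@pytest.fixture(scope="session")
def tiny_window() -> WindowConfig:
    """4,096 bp input with 16 x 128 bp central bins (flank 1,024 bp)."""
    return WindowConfig(input_length=4096, n_bins=16, bin_size=128)


@pytest.fixture(scope="session")
def tiny_extractor(tiny_window) -> SyntheticExtractor:
    return SyntheticExtractor(tiny_window, d=24, n_motifs=8, flank=32, seed=7)


@pytest.fixture(scope="session")
def coupled_dataset(tiny_window, tiny_extractor):
    """A small sequence-coupled simulated study used by several suites."""
    cfg = SimConfig(n=300, m=100, causal_per_gene=50, h_epi2=0.8, h_direct2=0.1, seed=42)
    return simulate_dataset(cfg, window_cfg=tiny_window, extractor=tiny_extractor)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
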