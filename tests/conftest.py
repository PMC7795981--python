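"""Shared fixtures: the default simulated run and its analysis products."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from fermnir import (
    SgSettings,
    SimulationConfig,
    run_mwpca,
    savgol,
    segment_stages,
    simulate_spectra,
    truncate,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def analyse(seed: int = 0, **config_overrides):
    """Run the standard analysis chain on a fresh simulation."""
    config = dataclasses.replace(SimulationConfig(), seed=seed, **config_overrides)
    series, ph = simulate_spectra(config)
    pre = truncate(savgol(truncate(series, 950.0, 1880.0), SgSettings()), 954.0, 1880.0)
    result = run_mwpca(pre, h_s=5)
    segmentation = segment_stages(result)
    return config, series, ph, pre, result, segmentation


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_run():
    """Config, raw series, pH profile, preprocessed series, MWPCA result, segmentation."""
    return analyse(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
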