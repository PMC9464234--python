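"""Shared fixtures: small seeded synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from pollenrecon import synthetic


@pytest.fixture(scope="session")
def demo_small():
    """A small but complete synthetic bundle (8 records, 150 surface samples)."""
    return synthetic.holocene_demo(seed=7, n_records=8, n_calib=150, n_samples=30)


@pytest.fixture(scope="session")
def calib_small(demo_small):
    return demo_small["calibration"]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
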