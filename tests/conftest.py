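import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hookqc as h

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_chip():
    """Degraded simulated chip under the standard study conditions:
    5000 probe sets, 30 % absent, tongs opening 0.5, moderate noise."""
    cfg = h.with_tongs_opening(h.SimConfig(n_psets=5000), 0.5)
    chip, truth = h.simulate_chip(cfg, seed=101)
    return chip, truth


@pytest.fixture(scope="session")
def default_result(default_chip):
    chip, _ = default_chip
    return h.analyze_chip(chip)


@pytest.fixture(scope="session")
def small_chip():
    """Smaller degraded chip for cheaper unit tests."""
    cfg = h.with_tongs_opening(h.SimConfig(n_psets=2000), 0.5)
    chip, truth = h.simulate_chip(cfg, seed=7)
    return chip, truth


@pytest.fixture(scope="session")
def small_result(small_chip):
    chip, _ = small_chip
    return h.analyze_chip(chip)


def make_chip(records):
    """Build a ChipData from (probeset_id, k, L, pm, mm) tuples."""
    df = pd.DataFrame(records, columns=["probeset_id", "k", "L", "pm", "mm"])
    return h.ChipData(df)


@pytest.fixture
def flat_chip():
    """Chip of identical intensities: no degradation signal anywhere."""
    recs = [
        (f"set{i}", k, 50 * (k - 1), 100.0, 100.0)
        for i in range(20)
        for k in range(1, 12)
    ]
    return make_chip(recs)
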