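"""Shared fixtures: small synthetic datasets with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from songqtl import synthetic_data as sd
from songqtl.qtl_scan import LodProfile


@pytest.fixture(scope="session")
def small_ril():
    """A compact RIL panel (80 lines, 5 x 20 windows) with one planted QTL."""
    cfg = sd.SimConfig(n_rils=80, windows_per_arm=20,
                       qtls=(sd.QtlSpec(window=50, effect_fraction=0.42),))
    panel, truth = sd.simulate_ril_panel(cfg, seed=101)
    records, table, t2 = sd.simulate_ril_traits(panel, cfg, seed=102)
    return cfg, panel, records, table, {**truth, **t2}


@pytest.fixture(scope="session")
def pop_panel_null():
    """10 FR vs 7 ZI strain table with correlated traits and no shift."""
    cfg = sd.SimConfig()
    table, truth = sd.simulate_population_panel(cfg, seed=103)
    return cfg, table, truth


def make_profile(lods, masked=None, threshold=None, arm="3R", width=1000):
    """Build a LodProfile from a plain LOD list (NaN where masked)."""
    lods = np.asarray(lods, dtype=float)
    if masked is None:
        masked = np.zeros(len(lods), dtype=bool)
    masked = np.asarray(masked, dtype=bool)
    arms = [arm] * len(lods) if isinstance(arm, str) else list(arm)
    win = pd.DataFrame({
        "arm": arms,
        "start": np.arange(len(lods)) * width,
        "end": (np.arange(len(lods)) + 1) * width,
        "lod": np.where(masked, np.nan, lods),
        "n": 100,
        "masked": masked,
    })
    return LodProfile(win, threshold=threshold)


@pytest.fixture
def profile_factory():
    return make_profile
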