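"""Shared fixtures: a small synthetic panel with its plates and truth."""

import numpy as np
import pandas as pd
import pytest

from uvcblink import synthetic
from uvcblink.matrix import FeatureMatrix


@pytest.fixture(scope="session")
def small_panel():
    """A seeded 25-substance panel with short series (fast to process)."""
    cfg = synthetic.PanelConfig(seed=7, series_length=6)
    panel, truth = synthetic.generate_feature_matrix(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def small_bioassay(small_panel):
    _, panel, truth = small_panel
    effect = synthetic.default_planted_effect(panel, truth, noise_cv=0.05)
    design = synthetic.PlateDesign(phenotypes_per_cell_type=2)
    return synthetic.generate_bioassay_plates(panel, effect, design, seed=7)


@pytest.fixture()
def tiny_matrix():
    """Hand-built 4-feature, 2-sample matrix for bookkeeping tests."""
    meta = pd.DataFrame(
        {"mz": [100.0, 150.0, 200.0, 250.0], "ccs": [120.0, 140.0, 160.0, 180.0]},
        index=pd.Index(["f1", "f2", "f3", "f4"], name="feature_id"),
    )
    ab = pd.DataFrame(
        {"s1": [6000.0, 3000.0, 800.0, 200.0], "s2": [9000.0, 100.0, 700.0, 200.0]},
        index=meta.index,
    )
    return FeatureMatrix(meta, ab)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
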