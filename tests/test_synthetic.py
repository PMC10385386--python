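import numpy as np
import pandas as pd
import pytest

from uvcblink import synthetic


def test_panel_reproducible_with_seed():
    cfg = synthetic.PanelConfig(seed=3, series_length=4)
    a, _ = synthetic.generate_feature_matrix(cfg)
    b, _ = synthetic.generate_feature_matrix(cfg)
    pd.testing.assert_frame_equal(a.abundance, b.abundance)
    pd.testing.assert_frame_equal(
        a.meta.drop(columns="formula"), b.meta.drop(columns="formula")
    )


def test_panel_seed_changes_data():
    a, _ = synthetic.generate_feature_matrix(synthetic.PanelConfig(seed=3, series_length=4))
    b, _ = synthetic.generate_feature_matrix(synthetic.PanelConfig(seed=4, series_length=4))
    assert not a.abundance.equals(b.abundance)


def test_panel_structure(small_panel):
    cfg, panel, truth = small_panel
    assert len(panel.samples) == cfg.n_substances
    assert set(truth.formula_map) == set(panel.feature_ids)
    # drivers form one CH2 series of 7 co-occurring features
    assert len(truth.driver_feature_ids) == 7
    sids = {truth.series_map[f] for f in truth.driver_feature_ids}
    assert len(sids) == 1


def test_subcategory_enrichment(small_panel):
    cfg, panel, truth = small_panel
    subs = truth.substances
    pct = panel.abundance / panel.abundance.sum(axis=0) * 100.0
    high = [f for f in panel.feature_ids if truth.series_map[f] in truth.high_dbe_series]
    share = pct.loc[high].sum(axis=0)
    cat2 = share[subs["category"] == "CAT2"].mean()
    cat1 = share[subs["category"] == "CAT1"].mean()
    assert cat2 > cat1  # PAC-enriched category carries more high-DBE abundance


def test_ccs_increases_with_mass_within_series(small_panel):
    _, panel, truth = small_panel
    meta = panel.meta.assign(series=[truth.series_map[f] for f in panel.feature_ids])
    for _, grp in meta.groupby("series"):
        g = grp.sort_values("mz")
        assert g["ccs"].is_monotonic_increasing


def test_bioassay_truth_consistency(small_bioassay):
    bio = small_bioassay
    # analytic EC10 below EC50 for a decreasing curve with 10% departure
    assert (bio.true_ec10 < bio.true_ec50).all().all()
    # higher burden -> lower EC50, same ordering on every endpoint
    for ep in bio.true_ec50.columns:
        r = np.corrcoef(bio.burden, np.log10(bio.true_ec50[ep]))[0, 1]
        assert r < -0.99


def test_plate_table_dialect(small_bioassay):
    plates = small_bioassay.plates
    assert {"plate_id", "well", "substance_id", "concentration_ug_per_ml",
            "endpoint", "raw_value", "well_role"} <= set(plates.columns)
    assert set(plates["well_role"]) >= {"test", "method_blank", "dmso"}
    assert (plates["raw_value"] >= 0).all()
    # duplicate plates present
    assert plates["plate_id"].nunique() == small_bioassay.design.n_plates


def test_neuron_concentration_range(small_bioassay):
    plates = small_bioassay.plates
    test = plates[plates["well_role"] == "test"]
    neuron = test[test["endpoint"].str.startswith("neuron")]
    other = test[~test["endpoint"].str.startswith("neuron")]
    assert neuron["concentration_ug_per_ml"].max() == 500.0
    assert other["concentration_ug_per_ml"].max() == 1000.0
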