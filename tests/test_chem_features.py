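import numpy as np
import pandas as pd
import pytest

from uvcblink import chem_features, synthetic
from uvcblink.chem_features import BIN_LABELS
from uvcblink.matrix import AnchorLibraryEntry, FeatureMatrix


def test_filter_matches_brute_force(small_panel):
    _, panel, _ = small_panel
    filtered = chem_features.filter_by_abundance(panel, 5000.0)
    expected = panel.abundance.index[(panel.abundance >= 5000.0).any(axis=1)]
    assert list(filtered.feature_ids) == list(expected)


def test_filter_keeps_feature_above_threshold_in_any_sample(tiny_matrix):
    filtered = chem_features.filter_by_abundance(tiny_matrix, 5000.0)
    assert list(filtered.feature_ids) == ["f1"]


def test_match_anchors_tolerances(tiny_matrix):
    lib = [
        AnchorLibraryEntry("hit", "C7H16", 100.0 + 100.0 * 4e-6, 120.5),
        AnchorLibraryEntry("ppm_out", "C8H18", 150.0 * (1 + 6e-6), 140.0),
        AnchorLibraryEntry("ccs_out", "C9H20", 200.0, 160.0 * 1.02),
    ]
    matched = chem_features.match_anchors(tiny_matrix, lib, 5.0, 1.0)
    assert set(matched) == {"f1"}
    assert matched["f1"].name == "hit"


def test_match_anchors_one_to_one_greedy():
    meta = pd.DataFrame(
        {"mz": [100.0, 100.0001], "ccs": [120.0, 120.0]},
        index=pd.Index(["a", "b"], name="feature_id"),
    )
    ab = pd.DataFrame({"s": [1.0, 1.0]}, index=meta.index)
    m = FeatureMatrix(meta, ab)
    lib = [AnchorLibraryEntry("x", "C7H16", 100.0, 120.0)]
    matched = chem_features.match_anchors(m, lib)
    assert set(matched) == {"a"}  # closer ppm wins, entry consumed


def test_match_anchors_brute_force_oracle(small_panel, rng):
    _, panel, truth = small_panel
    lib = synthetic.make_anchor_library(panel, truth)
    matched = chem_features.match_anchors(panel, lib, 5.0, 1.0)
    # every matched pair satisfies both tolerance gates
    for fid, entry in matched.items():
        row = panel.meta.loc[fid]
        assert abs(row["mz"] - entry.ref_mz) / entry.ref_mz * 1e6 <= 5.0
        assert abs(row["ccs"] - entry.ref_ccs) / entry.ref_ccs * 100.0 <= 1.0
    # one-to-one
    assert len({e.name for e in matched.values()}) == len(matched)


def test_series_and_formula_recovery(small_panel):
    _, panel, truth = small_panel
    filtered = chem_features.filter_by_abundance(panel, 5000.0)
    matches = chem_features.match_anchors(
        filtered, synthetic.make_anchor_library(panel, truth)
    )
    annotated, report = chem_features.assign_series_and_formulas(filtered, matches)
    got = {
        fid: f for fid, f in annotated.meta["formula"].items() if f is not None
    }
    correct = sum(truth.formula_map[fid] == f for fid, f in got.items())
    assert report.n_features_with_formula == len(got)
    assert correct / len(filtered.feature_ids) >= 0.95


def test_series_rejection_withholds_formulas():
    # two co-series features with CCS inverted vs mass -> rejected
    base_mz = 129.070425  # naphthalene [M+H]+ vicinity
    meta = pd.DataFrame(
        {"mz": [base_mz, base_mz + 14.0156500641], "ccs": [150.0, 140.0]},
        index=pd.Index(["a", "b"], name="feature_id"),
    )
    ab = pd.DataFrame({"s": [1.0, 1.0]}, index=meta.index)
    m = FeatureMatrix(meta, ab)
    lib = [AnchorLibraryEntry("naph", "C10H8", base_mz, 150.0)]
    matched = chem_features.match_anchors(m, lib)
    annotated, report = chem_features.assign_series_and_formulas(m, matched)
    assert report.rejected_series
    assert all(f is None for f in annotated.meta["formula"])


def test_percent_total_abundance_sums_to_100(small_panel):
    _, panel, _ = small_panel
    pct = chem_features.percent_total_abundance(panel)
    assert pct.units == "percent"
    np.testing.assert_allclose(pct.abundance.sum(axis=0), 100.0, atol=1e-9)


def test_bins_partition(tiny_matrix):
    pct = chem_features.percent_total_abundance(tiny_matrix)
    comp = chem_features.summarize_composition(pct)
    assert comp.bin_counts.sum(axis=1).eq(len(tiny_matrix.feature_ids)).all()
    np.testing.assert_allclose(comp.bin_abundance.sum(axis=1), 100.0, atol=1e-9)


def test_echa_flag_hand_case():
    # 41 features: one major plus 40 trace (<1% each)
    n_trace = 40
    meta = pd.DataFrame(
        {
            "mz": np.linspace(100.0, 500.0, n_trace + 1),
            "ccs": np.linspace(120.0, 260.0, n_trace + 1),
        },
        index=pd.Index([f"f{i}" for i in range(n_trace + 1)], name="feature_id"),
    )
    # s1: major at 85%, trace share 15% -> coverage 85 >= 80 -> True
    # s2: major at 70%, trace share 30% -> coverage 70 < 80 -> False
    ab = pd.DataFrame(
        {
            "s1": [85.0] + [15.0 / n_trace] * n_trace,
            "s2": [70.0] + [30.0 / n_trace] * n_trace,
        },
        index=meta.index,
    )
    pct = FeatureMatrix(meta, ab, units="percent")
    comp = chem_features.summarize_composition(pct)
    assert bool(comp.meets_echa_80["s1"]) is True
    assert bool(comp.meets_echa_80["s2"]) is False


def test_series_share_profiles(small_panel):
    _, panel, truth = small_panel
    filtered = chem_features.filter_by_abundance(panel, 5000.0)
    matches = chem_features.match_anchors(
        filtered, synthetic.make_anchor_library(panel, truth)
    )
    annotated, _ = chem_features.assign_series_and_formulas(filtered, matches)
    pct = chem_features.percent_total_abundance(annotated)
    raw = chem_features.series_share_profiles(pct, standardize=False)
    # shares partition the total percent abundance
    np.testing.assert_allclose(raw.sum(axis=1), 100.0, atol=1e-9)
    std = chem_features.series_share_profiles(pct)
    np.testing.assert_allclose(std.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(std.std(axis=0, ddof=1), 1.0, atol=1e-12)


def test_carbon_dbe_profile_columns(small_panel):
    _, panel, truth = small_panel
    filtered = chem_features.filter_by_abundance(panel, 5000.0)
    matches = chem_features.match_anchors(
        filtered, synthetic.make_anchor_library(panel, truth)
    )
    annotated, _ = chem_features.assign_series_and_formulas(filtered, matches)
    pct = chem_features.percent_total_abundance(annotated)
    prof = chem_features.carbon_dbe_profile(pct)
    assert {"n_C", "dbe"} <= set(prof.columns)
    assert (prof["dbe"] >= 0).all()
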