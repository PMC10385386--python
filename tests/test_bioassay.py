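import numpy as np
import pandas as pd
import pytest

from uvcblink import bioassay, synthetic
from uvcblink.bioassay import (
    CENSOR_FACTOR,
    DoseResponseSeries,
    HillFit,
    compute_pod_ec10,
    fit_hill,
    normalize_to_method_blank,
)


def _plate(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "plate_id", "well", "substance_id", "concentration_ug_per_ml",
            "endpoint", "raw_value", "well_role",
        ],
    )


def test_normalization_identity_blank_mean_is_100():
    plates = _plate([
        ("P1", 1, "", np.nan, "ep", 900.0, "method_blank"),
        ("P1", 2, "", np.nan, "ep", 1100.0, "method_blank"),
        ("P1", 3, "S1", 10.0, "ep", 1000.0, "test"),
    ])
    out = normalize_to_method_blank(plates)
    test = out[out["well_role"] == "test"]["normalized_value"]
    assert test.iloc[0] == pytest.approx(100.0)


def test_normalization_is_per_plate_and_endpoint():
    plates = _plate([
        ("P1", 1, "", np.nan, "a", 1000.0, "method_blank"),
        ("P1", 2, "S1", 1.0, "a", 500.0, "test"),
        ("P2", 1, "", np.nan, "a", 2000.0, "method_blank"),
        ("P2", 2, "S1", 1.0, "a", 500.0, "test"),
    ])
    out = normalize_to_method_blank(plates)
    vals = out[out["well_role"] == "test"]["normalized_value"].to_numpy()
    np.testing.assert_allclose(vals, [50.0, 25.0])


def test_normalization_requires_blanks():
    plates = _plate([("P1", 1, "S1", 1.0, "a", 500.0, "test")])
    with pytest.raises(ValueError, match="method-blank"):
        normalize_to_method_blank(plates)


def _series_from_hill(ec50, slope=1.5, concs=(1000, 100, 10, 1, 0.1)):
    c = np.array(sorted(concs))
    y = synthetic.hill_response(c, ec50, slope)
    return DoseResponseSeries("S", "ep", c, np.asarray(y))


def test_hill_fit_self_consistency():
    s = _series_from_hill(ec50=30.0)
    fit = fit_hill(s)
    assert fit.converged
    assert fit.ec50 == pytest.approx(30.0, rel=1e-4)
    assert fit.hill_slope == pytest.approx(1.5, rel=1e-4)


def test_hill_fit_flat_series_not_converged():
    c = np.array([0.1, 1.0, 10.0, 100.0])
    s = DoseResponseSeries("S", "ep", c, np.full(4, 100.0))
    assert not fit_hill(s).converged


def test_pod_matches_analytic_ec10():
    fit = HillFit(top=100.0, bottom=0.0, ec50=30.0, hill_slope=1.5, converged=True)
    pod, censored = compute_pod_ec10(fit, (0.1, 1000.0))
    assert not censored
    assert pod == pytest.approx(synthetic.analytic_ec10(30.0, 1.5), rel=1e-12)


def test_pod_right_censored_above_range():
    # EC50 so high no 10% departure occurs at or below c_max
    fit = HillFit(top=100.0, bottom=0.0, ec50=1e7, hill_slope=1.5, converged=True)
    pod, censored = compute_pod_ec10(fit, (0.1, 1000.0))
    assert censored
    assert pod == pytest.approx(1000.0 * CENSOR_FACTOR)


def test_pod_below_range_floored_not_censored():
    # very potent curve: EC10 below c_min must floor at c_min, never flip to
    # the inactive censoring value
    fit = HillFit(top=100.0, bottom=0.0, ec50=0.01, hill_slope=1.5, converged=True)
    pod, censored = compute_pod_ec10(fit, (0.1, 1000.0))
    assert not censored
    assert pod == pytest.approx(0.1)


def test_pod_flat_series_far_below_vehicle_floors_at_cmin():
    # fully responding at every tested concentration: flat fit near 0%
    c = np.array([0.1, 1.0, 10.0, 100.0, 1000.0])
    s = DoseResponseSeries("S", "ep", c, np.full(5, 2.0))
    fit = fit_hill(s)
    assert not fit.converged  # span below the floor
    pod, censored = compute_pod_ec10(fit, (0.1, 1000.0))
    assert not censored
    assert pod == pytest.approx(0.1)


def test_pod_flat_series_at_vehicle_right_censored():
    c = np.array([0.1, 1.0, 10.0, 100.0, 1000.0])
    s = DoseResponseSeries("S", "ep", c, np.full(5, 100.0))
    pod, censored = compute_pod_ec10(fit_hill(s), (0.1, 1000.0))
    assert censored
    assert pod == pytest.approx(1000.0 * CENSOR_FACTOR)


def test_pod_monotone_in_potency():
    pods = []
    for ec50 in (3.0, 30.0, 300.0):
        fit = HillFit(100.0, 0.0, ec50, 1.5, True)
        pod, _ = compute_pod_ec10(fit, (0.1, 1000.0))
        pods.append(pod)
    assert pods[0] < pods[1] < pods[2]


def test_pods_from_plates_pipeline(small_bioassay):
    pods, series = bioassay.pods_from_plates(small_bioassay.plates)
    wide = pods.wide()
    assert wide.shape[0] == small_bioassay.true_ec10.shape[0]
    assert (wide > 0).all().all()
    assert (pods.pod_min <= pods.pod_max).all()


def test_qc_vehicle_effect(small_bioassay):
    normalized = normalize_to_method_blank(small_bioassay.plates)
    qc = bioassay.qc_vehicle_effect(normalized)
    assert qc.passed, qc.reason


def test_qc_interplate_replicates(small_bioassay):
    normalized = normalize_to_method_blank(small_bioassay.plates)
    test = normalized[normalized["well_role"] == "test"]
    wide = test.pivot_table(
        index=["substance_id", "endpoint", "concentration_ug_per_ml"],
        columns="plate_id", values="normalized_value", aggfunc="mean",
    ).dropna()
    qc = bioassay.qc_interplate_replicates(wide["P1"], wide["P2"])
    assert qc.passed, qc.reason


def test_qc_interplate_replicates_fails_on_noise(rng):
    a = rng.normal(size=50)
    b = rng.normal(size=50)
    assert not bioassay.qc_interplate_replicates(a, b).passed
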