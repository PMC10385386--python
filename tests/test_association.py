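import numpy as np
import pandas as pd
import pytest

from uvcblink import association
from uvcblink.chem_features import percent_total_abundance
from uvcblink.matrix import FeatureMatrix


def _xy(rng, n=20, p=8, m=2):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     index=[f"S{i}" for i in range(n)],
                     columns=[f"f{j}" for j in range(p)])
    Y = pd.DataFrame(rng.normal(size=(n, m)), index=X.index,
                     columns=[f"y{k}" for k in range(m)])
    return X, Y


def test_lambda_grid_shape():
    g = association.DEFAULT_LAMBDA_GRID
    assert len(g) == 71
    assert g[0] == pytest.approx(0.1)
    assert g[-1] == pytest.approx(1e6)


def test_ridge_solve_matches_closed_form(rng):
    X = rng.normal(size=(25, 10))
    Y = rng.normal(size=(25, 2))
    lam = 3.7
    B = association.ridge_solve(X, Y, lam)
    expected = np.linalg.inv(X.T @ X + lam * np.eye(10)) @ X.T @ Y
    np.testing.assert_allclose(B, expected, rtol=1e-10)


def test_ridge_dual_equals_primal(rng):
    X = rng.normal(size=(15, 40))
    Y = rng.normal(size=(15, 3))
    for lam in (0.1, 10.0, 1000.0):
        np.testing.assert_allclose(
            association.ridge_solve(X, Y, lam),
            association.ridge_solve_dual(X, Y, lam),
            rtol=1e-9, atol=1e-12,
        )


def test_ridge_lambda_zero_requires_full_rank(rng):
    X = rng.normal(size=(10, 20))  # p > n: singular X'X
    Y = rng.normal(size=(10, 1))
    with pytest.raises(ValueError):
        association.ridge_solve(X, Y, 0.0)


def test_build_predictor_matrix_threshold_strict():
    meta = pd.DataFrame({"mz": [100.0, 200.0, 300.0],
                         "ccs": [120.0, 150.0, 180.0]},
                        index=pd.Index(["a", "b", "c"], name="feature_id"))
    ab = pd.DataFrame({"s1": [98.0, 1.0, 1.0], "s2": [98.0, 1.0, 1.0]},
                      index=meta.index)
    pct = FeatureMatrix(meta, ab, units="percent")
    with pytest.warns(UserWarning, match="zero-variance"):
        X = association.build_predictor_matrix(pct, 1.0)
    # b and c sit exactly at 1% -> excluded (strict >); a is constant -> dropped
    assert X.shape[1] == 0 or "a" not in X.columns


def test_loocv_exact_linear_signal(rng):
    # n > p, exact linear map: predictions nearly perfect at small lambda
    X, _ = _xy(rng, n=30, p=5, m=1)
    beta = rng.normal(size=(5, 1))
    Y = pd.DataFrame(X.to_numpy() @ beta, index=X.index, columns=["y"])
    res = association.loocv_predict(X, Y)
    assert res.r["y"] > 0.99


def test_loocv_null_r_near_zero(rng):
    X, Y = _xy(rng, n=25, p=200, m=2)
    res = association.loocv_predict(X, Y)
    assert res.r.abs().max() < 0.8  # no leakage artifact


def test_bh_qvalues_hand_computation():
    p = np.array([0.01, 0.04, 0.03, 0.005])
    q = association.bh_qvalues(p)
    # sorted p: 0.005, 0.01, 0.03, 0.04 -> q = p * n / rank with step-up min
    expected = np.array([0.02, 0.04, 0.04, 0.02])
    np.testing.assert_allclose(q, expected)


def test_bh_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        association.bh_qvalues(np.array([0.5, 1.5]))


def test_permutation_test_planted_signal(rng):
    X, _ = _xy(rng, n=25, p=30, m=1)
    beta = rng.normal(size=(30, 1))
    noise = rng.normal(scale=0.3, size=(25, 1))
    Y = pd.DataFrame(X.to_numpy() @ beta / np.sqrt(30) + noise,
                     index=X.index, columns=["y"])
    obs, perm = association.permutation_test(
        X, Y, n_perm=100, seed=5
    )
    assert perm.table.loc["y", "p"] < 0.05
    assert perm.table.loc["y", "q"] <= 1.0
    assert len(perm.null_r) == 100


def test_permutation_p_floor():
    # p can never be smaller than 1/(n_perm + 1)
    rng = np.random.default_rng(0)
    X, _ = _xy(rng, n=20, p=5, m=1)
    Y = pd.DataFrame(X.to_numpy()[:, :1] * 2.0, index=X.index, columns=["y"])
    _, perm = association.permutation_test(X, Y, n_perm=100, seed=1)
    assert perm.table["p"].min() >= 1.0 / 101.0


def test_influential_features_ranking(rng):
    X, _ = _xy(rng, n=25, p=6, m=1)
    scores = pd.DataFrame({"overall": X["f0"] * 3 + rng.normal(scale=0.1, size=25)})
    out = association.influential_features(X, scores)
    assert out.index[0] == "f0"
    assert abs(out.loc["f0", "overall"]) > 0.9


def test_reverse_prediction_runs(rng):
    X, Y = _xy(rng, n=15, p=4, m=2)
    res = association.reverse_prediction(Y, X)  # predict Y-cols from X? roles swapped inside
    assert res.cv_predictions.shape == Y.shape
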