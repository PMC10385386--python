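"""Multivariate ridge association between chemistry and bioactivity.

Fits the multivariate linear model ``Y = XB + error`` where ``X`` (n
substances x p features) and ``Y`` (n x m bioactivity responses) are
column-scaled matrices, with a single shared ridge penalty:

    B(lambda) = (X'X + lambda I)^-1 X'Y

The penalty is tuned on a log10 grid from -1.0 to 6.0 in 0.1 steps by
leave-one-out cross-validation, minimizing the pooled mean squared
prediction error.  Response columns are centered and scaled once on the
full data; predictor columns are, by default, centered and scaled inside
each CV fold (training-fold parameters applied to the held-out row).
Scaling X once on the full data, available via ``scale_in_fold=False``, is
degenerate when p >> n: full-data centering makes the held-out predictor
row equal minus the sum of the training rows, so small-penalty ridge
"predictions" reproduce the held-out response exactly and every CV
correlation approaches 1 regardless of signal.  The penalty is still
selected once, outside any outer loop, so a mild optimism remains; honesty
is restored by permutation inference: substance indices of Y are permuted
relative to X, the entire tuning + CV procedure is re-run per permutation,
and the observed prediction correlation r is converted to
``z = (r - E(r)) / SD(r)`` against the permutation null, with a two-sided
normal p-value and Benjamini-Hochberg q-values across responses.

Because n << p throughout, all fits go through the dual (kernel) form
``B = X'(XX' + lambda I)^-1 Y``; per-fold eigendecompositions of the
(n-1) x (n-1) Gram matrix are cached and reused across the whole penalty
grid and across permutations (Y changes, X does not), which makes the
1000-permutation protocol cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import FeatureMatrix

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "build_predictor_matrix",
    "scale_columns",
    "ridge_solve",
    "ridge_solve_dual",
    "loocv_predict",
    "prediction_correlation",
    "permutation_test",
    "bh_qvalues",
    "influential_features",
    "reverse_prediction",
    "RidgeResult",
    "PermutationResult",
]

#: log10(lambda) from -1.0 to 6.0 in increments of 0.1 (71 points).
DEFAULT_LAMBDA_GRID = 10.0 ** np.round(np.arange(-1.0, 6.0 + 1e-9, 0.1), 10)


def build_predictor_matrix(
    pct_matrix: FeatureMatrix, min_pct: float = 1.0
) -> pd.DataFrame:
    """Substances x features predictor matrix from a percent-normalized table.

    Retains features strictly above ``min_pct`` percent in at least one
    sample (a feature at exactly the threshold everywhere is dropped) and
    transposes to substances-as-rows.  Zero-variance columns are dropped
    with a warning since they cannot be scaled.
    """
    if pct_matrix.units != "percent":
        raise ValueError("predictor matrix must be built from percent units")
    keep = (pct_matrix.abundance > min_pct).any(axis=1)
    X = pct_matrix.abundance.loc[keep].T  # substances x features
    if X.shape[1] == 0:
        raise ValueError(f"no features exceed {min_pct}% in any sample")
    sds = X.std(axis=0, ddof=1)
    dead = sds[sds == 0].index
    if len(dead):
        warnings.warn(f"dropping {len(dead)} zero-variance feature(s): {list(dead)[:5]}")
        X = X.drop(columns=dead)
    return X


def scale_columns(M: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Center and scale each column to unit variance (n-1 denominator).

    Returns the scaled matrix plus the original means and SDs for
    back-transformation.  Zero-variance columns are dropped with a warning.
    """
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=1)
    dead = sds[sds == 0].index
    if len(dead):
        warnings.warn(f"dropping {len(dead)} zero-variance column(s)")
        M = M.drop(columns=dead)
        means = means.drop(dead)
        sds = sds.drop(dead)
    return (M - means) / sds, means, sds


def ridge_solve(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Primal ridge solution ``B = (X'X + lambda I)^-1 X'Y`` via a linear
    solve (no explicit inverse).  ``lambda = 0`` requires full-rank X'X."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = X.shape[1]
    A = X.T @ X + lam * np.eye(p)
    if lam == 0 and np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError(
            "X'X is singular at lambda=0; use a positive penalty"
        )
    return np.linalg.solve(A, X.T @ Y)


def ridge_solve_dual(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Dual (kernel) form ``B = X'(XX' + lambda I)^-1 Y``; identical to the
    primal solution, cheaper when n < p."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    return X.T @ np.linalg.solve(X @ X.T + lam * np.eye(n), Y)


# ---------------------------------------------------------------------------
# LOOCV machinery
# ---------------------------------------------------------------------------


def _fold_scale(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)  # constant-in-fold columns stay centered
    return mu, sd


class _LoocvCache:
    """Per-fold eigendecompositions of the leave-one-out Gram matrices.

    Depends only on X (and the X scaling mode), so it is shared across the
    penalty grid and across Y permutations.  ``scale_in_fold`` governs
    predictor scaling only; responses are always scaled once, outside.
    """

    def __init__(self, X: np.ndarray, scale_in_fold: bool = True):
        n = X.shape[0]
        self.n = n
        self.scale_in_fold = scale_in_fold
        self.folds = []
        idx = np.arange(n)
        if not scale_in_fold:
            mu, sd = _fold_scale(X)
            X = (X - mu) / sd
        for i in range(n):
            rest = idx[idx != i]
            Xm = X[rest]
            xi = X[i]
            if scale_in_fold:
                mu, sd = _fold_scale(Xm)
                Xm = (Xm - mu) / sd
                xi = (xi - mu) / sd
            K = Xm @ Xm.T
            d, U = np.linalg.eigh(K)
            g = (xi @ Xm.T) @ U  # row vector, length n-1
            self.folds.append((rest, d, U, g))

    def cv_predictions(self, Y: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
        """CV predictions for (already scaled) Y, shape (L, n, m)."""
        n, m = Y.shape
        L = len(lambdas)
        preds = np.empty((L, n, m))
        for i, (rest, d, U, g) in enumerate(self.folds):
            H = U.T @ Y[rest]  # (n-1) x m
            W = g[:, None] / (d[:, None] + lambdas[None, :])  # (n-1) x L
            preds[:, i, :] = W.T @ H
        return preds


@dataclass
class RidgeResult:
    """Tuned multivariate ridge fit with LOOCV predictions."""

    B: pd.DataFrame  # p x m coefficients at the selected penalty
    lambda_selected: float
    cv_predictions: pd.DataFrame  # n x m, original response scale
    r: pd.Series  # per-response Pearson(observed, cv-predicted)
    mspe: pd.Series  # pooled scaled-space MSPE per lambda
    y_means: pd.Series = field(repr=False, default=None)
    y_sds: pd.Series = field(repr=False, default=None)


def _as_2d(M) -> pd.DataFrame:
    if isinstance(M, pd.Series):
        return M.to_frame()
    return pd.DataFrame(M)


def loocv_predict(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    scale_in_fold: bool = True,
    _cache: _LoocvCache | None = None,
) -> RidgeResult:
    """Leave-one-out tuned multivariate ridge regression.

    ``X`` and ``Y`` are unscaled substances x columns tables with a shared
    row order; each row is predicted from a model fitted on the remaining
    rows and the penalty minimizing the pooled (per-response standardized)
    MSPE over the grid is selected.  Predictions are returned on the
    original Y scale.  See the module docstring for the two scaling modes.
    """
    X, Y = _as_2d(X), _as_2d(Y)
    if len(X) != len(Y):
        raise ValueError("X and Y must have the same number of substances")
    if len(X) < 3:
        raise ValueError("need n >= 3 for leave-one-out evaluation")
    lambda_grid = np.asarray(lambda_grid, float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")

    Xs, _, _ = scale_columns(X)
    Ys, y_means, y_sds = scale_columns(Y)
    Xa = X[Xs.columns].to_numpy(float)

    cache = _cache if _cache is not None else _LoocvCache(Xa, scale_in_fold)
    Ya = Ys.to_numpy()  # response scaling is done once, on the full data
    preds = cache.cv_predictions(Ya, lambda_grid)  # (L, n, m), scaled space
    mspe = ((preds - Ya[None]) ** 2).mean(axis=(1, 2))
    best = int(np.argmin(mspe))
    lam = float(lambda_grid[best])

    cv_orig = preds[best] * y_sds.to_numpy()[None, :] + y_means.to_numpy()[None, :]
    cv_df = pd.DataFrame(cv_orig, index=Y.index, columns=Ys.columns)
    r = prediction_correlation(Y[Ys.columns], cv_df)

    B = pd.DataFrame(
        ridge_solve_dual(Xs.to_numpy(), Ys.to_numpy(), lam),
        index=Xs.columns, columns=Ys.columns,
    )
    return RidgeResult(
        B=B,
        lambda_selected=lam,
        cv_predictions=cv_df,
        r=r,
        mspe=pd.Series(mspe, index=lambda_grid, name="mspe"),
        y_means=y_means,
        y_sds=y_sds,
    )


def prediction_correlation(observed: pd.DataFrame, predicted: pd.DataFrame) -> pd.Series:
    """Pearson r per response between observed and CV-predicted values.

    Constant vectors make r undefined; such responses are recorded as 0.
    """
    observed, predicted = _as_2d(observed), _as_2d(predicted)
    out = {}
    for col in observed.columns:
        o = observed[col].to_numpy(float)
        p = predicted[col].to_numpy(float)
        if np.ptp(o) == 0 or np.ptp(p) == 0:
            out[col] = 0.0
        else:
            out[col] = float(np.corrcoef(o, p)[0, 1])
    return pd.Series(out, name="r")


def bh_qvalues(pvals: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up q-values (monotone, in (0, 1])."""
    arr = np.asarray(pvals, float)
    if ((arr <= 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvals, pd.Series):
        return pd.Series(q, index=pvals.index, name="q")
    return q


@dataclass
class PermutationResult:
    """Permutation inference on per-response prediction correlations."""

    table: pd.DataFrame  # per response: r, null_mean, null_sd, z, p, q
    null_r: pd.DataFrame  # n_perm x m null correlations
    n_perm: int
    seed: int
    lambda_selected: float


def _null_permutation(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform permutation of 0..n-1 excluding the identity."""
    while True:
        perm = rng.permutation(n)
        if not np.array_equal(perm, np.arange(n)):
            return perm


def permutation_test(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_perm: int = 1000,
    seed: int = 0,
    reselect_lambda: bool = True,
    scale_in_fold: bool = True,
) -> tuple[RidgeResult, PermutationResult]:
    """Permutation z-test on the CV prediction correlations.

    Substance indices of Y are shuffled relative to X ``n_perm`` times
    (identity excluded); for each permutation the full tuning + LOOCV
    procedure is re-run (or, with ``reselect_lambda=False``, the observed
    penalty is reused) and the null r values collected.  The observed r is
    reduced to ``z = (r - E(r)) / SD(r)`` and referred to a standard normal
    in a two-sided test; p-values are floored at ``1/(n_perm + 1)`` and BH
    q-values computed across responses.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X, Y = _as_2d(X), _as_2d(Y)
    Xs, _, _ = scale_columns(X)
    cache = _LoocvCache(X[Xs.columns].to_numpy(float), scale_in_fold)
    observed = loocv_predict(X, Y, lambda_grid, _cache=cache)

    grid = np.asarray(lambda_grid, float)
    perm_grid = grid if reselect_lambda else np.array([observed.lambda_selected])
    Ys, _, _ = scale_columns(Y)
    Ya = Ys.to_numpy()  # full-data response scaling is permutation-invariant
    rng = np.random.default_rng(seed)
    n = len(X)
    null = np.empty((n_perm, Ya.shape[1]))
    for b in range(n_perm):
        perm = _null_permutation(rng, n)
        Yp = Ya[perm]
        preds = cache.cv_predictions(Yp, perm_grid)
        mspe = ((preds - Yp[None]) ** 2).mean(axis=(1, 2))
        best = preds[int(np.argmin(mspe))]
        for j in range(Ya.shape[1]):
            o, p = Yp[:, j], best[:, j]
            null[b, j] = 0.0 if (np.ptp(o) == 0 or np.ptp(p) == 0) else np.corrcoef(o, p)[0, 1]

    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    if (null_sd == 0).any():
        raise ValueError("degenerate permutation null: SD(r) = 0 for some response")
    r_obs = observed.r.to_numpy()
    z = (r_obs - null_mean) / null_sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.maximum(p, 1.0 / (n_perm + 1))
    q = bh_qvalues(p)
    table = pd.DataFrame(
        {
            "r": r_obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p": p,
            "q": q,
        },
        index=observed.r.index,
    )
    perm_result = PermutationResult(
        table=table,
        null_r=pd.DataFrame(null, columns=observed.r.index),
        n_perm=n_perm,
        seed=seed,
        lambda_selected=observed.lambda_selected,
    )
    return observed, perm_result


def influential_features(
    X_unscaled: pd.DataFrame, scores: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature Pearson correlation with each bioactivity score.

    ``scores`` is substances x score columns (cell-type scores plus an
    ``overall`` column); rows share order with ``X_unscaled``.  Returns one
    row per feature with a signed r per score, ranked by |r| against the
    overall score (first column when no ``overall`` column exists).
    Constant features get r = 0 and a flag.
    """
    if not X_unscaled.index.equals(scores.index):
        raise ValueError("X and scores must share substance order")
    rank_col = "overall" if "overall" in scores.columns else scores.columns[0]
    rows = {}
    flat = {}
    for feat in X_unscaled.columns:
        x = X_unscaled[feat].to_numpy(float)
        rs = {}
        for col in scores.columns:
            s = scores[col].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(s) == 0:
                rs[col] = 0.0
            else:
                rs[col] = float(np.corrcoef(x, s)[0, 1])
        rows[feat] = rs
        flat[feat] = np.ptp(x) == 0
    out = pd.DataFrame(rows).T
    out["constant_feature"] = pd.Series(flat)
    out = out.sort_values(rank_col, key=lambda s: s.abs(), ascending=False)
    out.index.name = "feature_id"
    return out


def reverse_prediction(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> RidgeResult:
    """Run the identical tuned-LOOCV machinery with roles swapped,
    predicting chemical features from bioactivity."""
    return loocv_predict(Y, X, lambda_grid)
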