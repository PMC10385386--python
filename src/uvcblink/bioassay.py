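"""Concentration-response processing: normalization, QC, Hill fits, EC10 PODs.

Raw plate readouts are normalized to the average of the method-blank
(vehicle) wells on the same plate and endpoint, expressed as percent
response; after normalization the vehicle level is 100%.  Each substance x
endpoint series is fitted with a four-parameter Hill curve and the point of
departure (POD) is the lowest concentration at which the fitted curve
departs 10% from the vehicle mean (EC10), in either direction.  Series
with no 10% departure inside the tested range are censored at ten times
the highest tested concentration (one log above the range), which maps
them to the least-bioactive end of downstream potency scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "normalize_to_method_blank",
    "qc_vehicle_effect",
    "qc_interplate_replicates",
    "qc_intraplate_replicates",
    "extract_series",
    "fit_hill",
    "compute_pod_ec10",
    "pods_from_plates",
    "DoseResponseSeries",
    "HillFit",
    "PODTable",
]

CENSOR_FACTOR = 10.0  # censored PODs sit one log above the tested range


def normalize_to_method_blank(plates: pd.DataFrame) -> pd.DataFrame:
    """Express raw well values as percent of the plate x endpoint method blank.

    ``normalized = raw / mean(method-blank wells of the same plate and
    endpoint) x 100``, applied to every well including controls.  Raises
    when a plate x endpoint lacks blank wells or their mean is ~0.
    """
    out = plates.copy()
    normalized = np.empty(len(out))
    for (plate, ep), idx in out.groupby(["plate_id", "endpoint"]).groups.items():
        sub = out.loc[idx]
        blanks = sub.loc[sub["well_role"] == "method_blank", "raw_value"]
        if blanks.empty:
            raise ValueError(f"no method-blank wells on plate {plate}, endpoint {ep}")
        bmean = blanks.mean()
        if abs(bmean) < 1e-12:
            raise ValueError(
                f"method-blank mean ~0 on plate {plate}, endpoint {ep}"
            )
        normalized[out.index.get_indexer(idx)] = sub["raw_value"] / bmean * 100.0
    out["normalized_value"] = normalized
    return out


@dataclass
class QCResult:
    passed: bool
    reason: str
    details: pd.DataFrame | dict | None = None


def qc_vehicle_effect(
    normalized: pd.DataFrame, band_pct: float = 10.0
) -> QCResult:
    """Check that the vehicle itself is inert.

    Compares method-blank, DMSO and media control means per endpoint; passes
    iff every pairwise mean difference is within ``band_pct`` percent of the
    media mean.
    """
    roles = ("method_blank", "dmso", "media")
    recs = []
    ok = True
    reasons = []
    for ep, sub in normalized.groupby("endpoint"):
        means = {}
        for role in roles:
            vals = sub.loc[sub["well_role"] == role, "normalized_value"]
            if vals.empty:
                return QCResult(False, f"missing control role {role} for {ep}")
            means[role] = vals.mean()
        band = band_pct / 100.0 * abs(means["media"])
        worst = max(
            abs(means[a] - means[b]) for a in roles for b in roles
        )
        ep_ok = worst <= band
        ok &= ep_ok
        if not ep_ok:
            reasons.append(f"{ep}: max control difference {worst:.2f} > band {band:.2f}")
        recs.append((ep, *[means[r] for r in roles], worst, ep_ok))
    details = pd.DataFrame(
        recs, columns=["endpoint", *roles, "max_abs_diff", "passed"]
    ).set_index("endpoint")
    return QCResult(ok, "; ".join(reasons) if reasons else "all controls within band", details)


def qc_interplate_replicates(
    rep1: np.ndarray, rep2: np.ndarray, r_threshold: float = 0.8, alpha: float = 0.05
) -> QCResult:
    """Reproducibility gate for duplicate plates.

    Passes iff Pearson's r and Spearman's rho between paired values both
    exceed ``r_threshold`` with significant p-values.
    """
    rep1 = np.asarray(rep1, dtype=float)
    rep2 = np.asarray(rep2, dtype=float)
    if rep1.shape != rep2.shape or rep1.size < 3:
        raise ValueError("need equal-length paired vectors with n >= 3")
    if np.ptp(rep1) == 0 or np.ptp(rep2) == 0:
        return QCResult(False, "constant replicate vector: correlation undefined",
                        {"pearson_r": np.nan, "spearman_rho": np.nan})
    pr = stats.pearsonr(rep1, rep2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sr = stats.spearmanr(rep1, rep2)
    passed = (
        pr.statistic > r_threshold
        and sr.statistic > r_threshold
        and pr.pvalue < alpha
        and sr.pvalue < alpha
    )
    details = {
        "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
    }
    reason = "reproducible" if passed else (
        f"r={pr.statistic:.3f}, rho={sr.statistic:.3f} "
        f"(threshold {r_threshold}, p<{alpha} required)"
    )
    return QCResult(passed, reason, details)


@dataclass
class DoseResponseSeries:
    """One substance x endpoint concentration series in percent units."""

    substance_id: str
    endpoint_id: str
    concentrations: np.ndarray  # µg/mL, ascending
    responses: np.ndarray  # % of vehicle, same length
    replicate: str = "pooled"

    def __post_init__(self) -> None:
        order = np.argsort(self.concentrations, kind="stable")
        self.concentrations = np.asarray(self.concentrations, dtype=float)[order]
        self.responses = np.asarray(self.responses, dtype=float)[order]
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be positive")
        if not np.isfinite(self.responses).all():
            raise ValueError("responses must be finite")


def extract_series(
    normalized: pd.DataFrame, pool_replicates: bool = True
) -> list[DoseResponseSeries]:
    """Collect test wells into per-substance x endpoint series.

    With ``pool_replicates`` all wells across plates and intra-plate
    replicates are pooled into one series (the default for POD derivation);
    otherwise one series per plate is returned, tagged by plate id.
    """
    test = normalized[(normalized["well_role"] == "test") & (normalized["substance_id"] != "")]
    keys = ["substance_id", "endpoint"] if pool_replicates else [
        "substance_id", "endpoint", "plate_id"
    ]
    series = []
    for key, sub in test.groupby(keys):
        series.append(
            DoseResponseSeries(
                substance_id=key[0],
                endpoint_id=key[1],
                concentrations=sub["concentration_ug_per_ml"].to_numpy(),
                responses=sub["normalized_value"].to_numpy(),
                replicate="pooled" if pool_replicates else key[2],
            )
        )
    return series


@dataclass
class HillFit:
    top: float
    bottom: float
    ec50: float
    hill_slope: float
    converged: bool
    sse: float = np.nan

    @property
    def decreasing(self) -> bool:
        return self.top >= self.bottom

    def predict(self, c: np.ndarray | float) -> np.ndarray | float:
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (np.asarray(c, dtype=float) / self.ec50) ** self.hill_slope
        )


def _hill_model(logc: np.ndarray, top: float, bottom: float, log_ec50: float, slope: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (logc - log_ec50)))


def fit_hill(
    series: DoseResponseSeries,
    span_floor: float = 5.0,
    slope_bounds: tuple[float, float] = (0.1, 10.0),
    n_starts: int = 3,
) -> HillFit:
    """Least-squares four-parameter Hill fit on log10 concentration.

    ``R(c) = bottom + (top - bottom) / (1 + (c/ec50)^slope)`` with slope
    constrained positive; a rising response is captured by ``top < bottom``.
    Multi-start (EC50 initialized at the low, mid and high end of the tested
    range) to reduce local-minimum risk.  ``converged=False`` when the
    observed response span is below ``span_floor`` percent (flat series) or
    the optimizer fails.
    """
    c = series.concentrations
    y = series.responses
    if len(np.unique(c)) < 4:
        raise ValueError("need >= 4 distinct concentrations for a Hill fit")
    span = float(y.max() - y.min())
    if span < span_floor:
        return HillFit(float(y.mean()), float(y.mean()), np.nan, np.nan, False)

    logc = np.log10(c)
    lo, hi = logc.min(), logc.max()
    # orientation guess: responses at high c below those at low c -> decreasing
    y_lo = y[logc <= np.quantile(logc, 0.34)].mean()
    y_hi = y[logc >= np.quantile(logc, 0.66)].mean()
    best = None
    bounds = (
        [-500.0, -500.0, lo - 3.0, slope_bounds[0]],
        [500.0, 500.0, hi + 3.0, slope_bounds[1]],
    )
    for start in np.linspace(lo, hi, n_starts):
        p0 = [y_lo, y_hi, start, 1.0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    _hill_model, logc, y, p0=p0, bounds=bounds, maxfev=20000
                )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - _hill_model(logc, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return HillFit(np.nan, np.nan, np.nan, np.nan, False)
    (top, bottom, log_ec50, slope), sse = best
    fit = HillFit(float(top), float(bottom), float(10.0**log_ec50), float(slope), True, sse)
    if abs(fit.top - fit.bottom) < span_floor:
        fit.converged = False
    return fit


def compute_pod_ec10(
    fit: HillFit,
    design_range: tuple[float, float],
    vehicle_mean: float = 100.0,
    departure: float = 10.0,
) -> tuple[float, bool]:
    """EC10 point of departure by analytic inversion of the fitted Hill curve.

    The POD is the smallest concentration in the tested range where the
    fitted response departs ``departure`` percent from the vehicle mean, in
    either direction.  Returns ``(pod, censored)``.  A series with no 10%
    departure anywhere in or below the tested range (including
    non-converged fits flat near the vehicle level) is right-censored at
    ``CENSOR_FACTOR x`` the highest tested concentration, mapping it to the
    least-bioactive end of downstream scaling.  A curve already departed at
    the lowest tested concentration — including a flat series far from the
    vehicle level, i.e. fully responding at every tested concentration — is
    floored at that concentration (maximal observed potency must not be
    confused with inactivity).
    """
    c_min, c_max = design_range
    censor_value = c_max * CENSOR_FACTOR
    if not fit.converged:
        # a flat fit stores the series level in top; far from vehicle
        # means the response plateaued below the tested range
        if np.isfinite(fit.top) and abs(fit.top - vehicle_mean) >= departure:
            return c_min, False
        return censor_value, True
    crossings = []
    for target in (vehicle_mean - departure, vehicle_mean + departure):
        # solve bottom + (top-bottom)/(1+(c/ec50)^s) = target
        denom = target - fit.bottom
        if denom == 0:
            continue
        ratio = (fit.top - target) / denom
        if ratio <= 0:
            continue  # target outside the curve's span
        c = fit.ec50 * ratio ** (1.0 / fit.hill_slope)
        if np.isfinite(c) and c <= c_max:
            crossings.append(c)
    if not crossings:
        return censor_value, True
    return float(max(min(crossings), c_min)), False


@dataclass
class PODTable:
    """Long-format POD table plus per-endpoint extremes.

    ``table`` columns: substance_id, endpoint, pod, censored.  ``pod_min``
    and ``pod_max`` are per-endpoint extremes across substances (censored
    values included at their censoring value), the scaling anchors of the
    downstream potency index.
    """

    table: pd.DataFrame
    pod_min: pd.Series
    pod_max: pd.Series

    def wide(self) -> pd.DataFrame:
        return self.table.pivot(index="substance_id", columns="endpoint", values="pod")


def pods_from_plates(
    plates: pd.DataFrame, span_floor: float = 5.0
) -> tuple[PODTable, list[DoseResponseSeries]]:
    """Raw plates -> normalized series -> Hill fits -> EC10 POD table."""
    normalized = normalize_to_method_blank(plates)
    series = extract_series(normalized)
    rows = []
    for s in series:
        fit = fit_hill(s, span_floor=span_floor)
        rng = (float(s.concentrations.min()), float(s.concentrations.max()))
        pod, censored = compute_pod_ec10(fit, rng)
        rows.append((s.substance_id, s.endpoint_id, pod, censored))
    table = pd.DataFrame(rows, columns=["substance_id", "endpoint", "pod", "censored"])
    pod_min = table.groupby("endpoint")["pod"].min()
    pod_max = table.groupby("endpoint")["pod"].max()
    return PODTable(table, pod_min, pod_max), series


def qc_intraplate_replicates(
    normalized: pd.DataFrame, max_log10_ec50_diff: float = 0.5
) -> QCResult:
    """Consistency of substances plated twice on the same plate.

    Fits each within-plate replicate curve separately; passes iff fitted
    EC50s of every replicated substance x endpoint agree within
    ``max_log10_ec50_diff`` decades.
    """
    test = normalized[(normalized["well_role"] == "test") & (normalized["substance_id"] != "")]
    recs = []
    ok = True
    for (plate, s, ep), sub in test.groupby(["plate_id", "substance_id", "endpoint"]):
        n_per_conc = sub.groupby("concentration_ug_per_ml").size()
        if n_per_conc.min() < 2:
            continue  # not replicated within this plate
        halves = []
        for conc, wells in sub.groupby("concentration_ug_per_ml"):
            halves.append(wells.sort_values("well"))
        first = pd.concat(h.iloc[[0]] for h in halves)
        second = pd.concat(h.iloc[[1]] for h in halves)
        fits = []
        for rep in (first, second):
            ser = DoseResponseSeries(
                s, ep, rep["concentration_ug_per_ml"].to_numpy(),
                rep["normalized_value"].to_numpy(),
            )
            fits.append(fit_hill(ser))
        if not all(f.converged for f in fits):
            continue
        diff = abs(np.log10(fits[0].ec50) - np.log10(fits[1].ec50))
        passed = diff <= max_log10_ec50_diff
        ok &= passed
        recs.append((plate, s, ep, diff, passed))
    details = pd.DataFrame(
        recs, columns=["plate_id", "substance_id", "endpoint", "log10_ec50_diff", "passed"]
    )
    return QCResult(ok, "intra-plate replicates consistent" if ok else "EC50 drift", details)
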