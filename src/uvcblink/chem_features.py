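"""Nontarget IMS-MS feature characterization.

Filtering, anchor matching, Kendrick-mass-defect homologous-series
organization, formula propagation with CCS validation, percent-of-total
normalization, abundance binning and composition summaries.

Conventions
-----------
* Feature m/z values are treated as protonated molecules; the proton mass
  is subtracted before Kendrick / formula arithmetic (``proton_offset=0``
  switches to the M+. charge-exchange convention).
* Tolerance boundaries are inclusive: a feature exactly 5 ppm from a
  library value still matches.
* KMD uses the petroleomics convention ``round(KM) - KM``; members of an
  exact CH2 series share it to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formula import (
    CH2_MASS,
    MASS_PROTON,
    MolecularFormula,
    compute_dbe,
    kendrick_mass_defect,
)
from .matrix import AnchorLibraryEntry, FeatureMatrix

__all__ = [
    "filter_by_abundance",
    "match_anchors",
    "assign_series_and_formulas",
    "percent_total_abundance",
    "summarize_composition",
    "neat_extract_overlap",
    "carbon_dbe_profile",
    "typical_constituent_report",
    "CompositionSummary",
    "compute_dbe",
    "kendrick_mass_defect",
]


def filter_by_abundance(matrix: FeatureMatrix, threshold: float = 5000.0) -> FeatureMatrix:
    """Retain features whose maximum abundance across samples meets the
    threshold (default 5000 counts), suppressing noise-level features.

    A feature is kept iff its abundance is >= ``threshold`` in at least one
    sample; the sample set is unchanged.  Idempotent.
    """
    keep = matrix.abundance.max(axis=1) >= threshold
    return matrix.subset(matrix.feature_ids[keep])


def match_anchors(
    matrix: FeatureMatrix,
    library: list[AnchorLibraryEntry],
    ppm_tol: float = 5.0,
    ccs_tol_pct: float = 1.0,
) -> dict[str, AnchorLibraryEntry]:
    """Match features to known-constituent library entries.

    A feature is eligible for an entry iff both ``|mz - ref_mz|/ref_mz * 1e6
    <= ppm_tol`` and ``|ccs - ref_ccs|/ref_ccs * 100 <= ccs_tol_pct``.
    Assignment is one-to-one greedy by ppm distance (ties broken by CCS
    distance).  Returns ``{feature_id: entry}``.
    """
    if ppm_tol <= 0 or ccs_tol_pct <= 0:
        raise ValueError("tolerances must be positive")
    candidates = []
    for fid, row in matrix.meta.iterrows():
        for entry in library:
            ppm = abs(row["mz"] - entry.ref_mz) / entry.ref_mz * 1e6
            ccs_pct = abs(row["ccs"] - entry.ref_ccs) / entry.ref_ccs * 100.0
            if ppm <= ppm_tol and ccs_pct <= ccs_tol_pct:
                candidates.append((ppm, ccs_pct, fid, entry))
    candidates.sort(key=lambda t: (t[0], t[1], t[2], t[3].name))
    matched: dict[str, AnchorLibraryEntry] = {}
    used_entries: set[str] = set()
    for ppm, ccs_pct, fid, entry in candidates:
        if fid in matched or entry.name in used_entries:
            continue
        matched[fid] = entry
        used_entries.add(entry.name)
    return matched


@dataclass
class SeriesReport:
    """Outcome of homologous-series assignment."""

    n_series: int
    anchored_series: list[int]
    rejected_series: list[int]  # failed CCS-vs-mass monotonicity
    n_features_with_formula: int


def assign_series_and_formulas(
    matrix: FeatureMatrix,
    anchor_matches: dict[str, AnchorLibraryEntry],
    kmd_tol: float = 0.0005,
    ppm_tol: float = 5.0,
    proton_offset: float = MASS_PROTON,
) -> tuple[FeatureMatrix, SeriesReport]:
    """Organize features into CH2 homologous series and propagate formulas.

    Features are grouped by Kendrick mass defect of the neutral mass
    (single-linkage within ``kmd_tol``).  Within a series containing an
    anchor-matched feature, each member's formula is the anchor formula
    plus/minus an integer number of CH2 units, accepted only when the mass
    residual is within ``ppm_tol``.  A series whose CCS is not strictly
    increasing with mass fails validation: its features keep their
    ``series_id`` but formulas are withheld.
    """
    if not anchor_matches:
        raise ValueError("at least one anchored feature is required")
    out = matrix.copy()
    neutral = out.meta["mz"] - proton_offset
    kmd = neutral.map(lambda m: kendrick_mass_defect(m)[1])

    order = kmd.sort_values().index
    series_of: dict[str, int] = {}
    sid = 0
    prev = None
    for fid in order:
        if prev is not None and kmd[fid] - kmd[prev] > kmd_tol:
            sid += 1
        series_of[fid] = sid
        prev = fid
    out.meta["series_id"] = pd.array(
        [series_of[f] for f in out.meta.index], dtype="Int64"
    )

    formulas: dict[str, MolecularFormula | None] = {f: None for f in out.meta.index}
    anchored, rejected = [], []
    for s in range(sid + 1):
        members = [f for f in out.meta.index if series_of[f] == s]
        anchors_here = [(f, anchor_matches[f]) for f in members if f in anchor_matches]
        if not anchors_here:
            continue
        # reference anchor: smallest ppm error vs its library entry
        ref_fid, ref_entry = min(
            anchors_here,
            key=lambda t: abs(out.meta.loc[t[0], "mz"] - t[1].ref_mz) / t[1].ref_mz,
        )
        anchored.append(s)
        ref_neutral = out.meta.loc[ref_fid, "mz"] - proton_offset
        proposal: dict[str, MolecularFormula] = {}
        for f in members:
            m = out.meta.loc[f, "mz"] - proton_offset
            k = round((m - ref_neutral) / CH2_MASS)
            residual = abs(m - (ref_neutral + k * CH2_MASS))
            if residual / m * 1e6 > ppm_tol:
                continue
            cand = ref_entry.formula.add_ch2(int(k))
            if cand.n_C >= 1 and cand.n_H >= 0:
                proposal[f] = cand
        # validation: CCS strictly increasing with mass over proposed members
        sub = out.meta.loc[list(proposal)].sort_values("mz")
        if len(sub) >= 2 and not np.all(np.diff(sub["ccs"].to_numpy()) > 0):
            rejected.append(s)
            continue
        formulas.update(proposal)

    out.meta["formula"] = [formulas[f] for f in out.meta.index]
    report = SeriesReport(
        n_series=sid + 1,
        anchored_series=anchored,
        rejected_series=rejected,
        n_features_with_formula=sum(v is not None for v in formulas.values()),
    )
    return out, report


def percent_total_abundance(matrix: FeatureMatrix) -> FeatureMatrix:
    """Normalize each sample's abundances to percent of its total.

    Every per-sample column sums to 100 afterwards; applied after the
    abundance filter, so percentages are of filtered features.
    """
    totals = matrix.abundance.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero total abundance in sample(s): {list(zero.index)}")
    out = matrix.copy()
    out.abundance = matrix.abundance / totals * 100.0
    out.units = "percent"
    return out


#: Half-open abundance bins, percent of total: majors, minors, traces.
BIN_LABELS = (">=1%", "0.1-1%", "<0.1%")


def _bin_of(pct: np.ndarray) -> np.ndarray:
    out = np.full(pct.shape, BIN_LABELS[2], dtype=object)
    out[(pct >= 0.1) & (pct < 1.0)] = BIN_LABELS[1]
    out[pct >= 1.0] = BIN_LABELS[0]
    return out


@dataclass
class CompositionSummary:
    """Per-sample composition bookkeeping.

    ``bin_abundance`` gives the summed percent abundance per sample in each
    of the three half-open bins [1, inf), [0.1, 1), [0, 0.1); rows sum to
    100.  ``coverage_ge1pct`` is the share of abundance carried by >=1%
    features — the quantity the ECHA 80%-characterization rule is applied
    to (``meets_echa_80``).
    """

    bin_abundance: pd.DataFrame  # samples x 3 bins, percent
    bin_counts: pd.DataFrame  # samples x 3 bins, feature counts
    feature_bins: pd.DataFrame  # features x samples, bin labels
    coverage_ge1pct: pd.Series
    meets_echa_80: pd.Series


def summarize_composition(pct_matrix: FeatureMatrix, echa_threshold: float = 80.0) -> CompositionSummary:
    """Bin features per sample into {>=1%, 0.1-1%, <0.1%} and evaluate the
    80%-coverage characterization rule.
    """
    if pct_matrix.units != "percent":
        raise ValueError("summarize_composition expects a percent-normalized matrix")
    pct = pct_matrix.abundance
    labels = pd.DataFrame(
        _bin_of(pct.to_numpy()), index=pct.index, columns=pct.columns
    )
    bin_ab = pd.DataFrame(
        {b: pct.where(labels == b, 0.0).sum(axis=0) for b in BIN_LABELS}
    )
    bin_ct = pd.DataFrame({b: (labels == b).sum(axis=0) for b in BIN_LABELS})
    coverage = bin_ab[BIN_LABELS[0]]
    return CompositionSummary(
        bin_abundance=bin_ab,
        bin_counts=bin_ct,
        feature_bins=labels,
        coverage_ge1pct=coverage,
        meets_echa_80=coverage >= echa_threshold,
    )


def neat_extract_overlap(
    neat_pct: FeatureMatrix, extract_pct: FeatureMatrix
) -> pd.DataFrame:
    """Shared vs unique abundance between a neat substance and its extract.

    Features are matched across the two matrices by assigned molecular
    formula; unannotated features count as unique.  Returns one row per
    sample common to both matrices with the percent abundance carried by
    shared formulas and by formulas unique to each side.
    """
    def formula_set(m: FeatureMatrix) -> set:
        return {f for f in m.meta["formula"] if f is not None}

    shared = formula_set(neat_pct) & formula_set(extract_pct)
    samples = [s for s in neat_pct.samples if s in extract_pct.samples]
    rows = []
    for s in samples:
        def split(m: FeatureMatrix) -> tuple[float, float]:
            in_shared = m.meta["formula"].map(
                lambda f: f is not None and f in shared
            ).to_numpy()
            col = m.abundance[s].to_numpy()
            return float(col[in_shared].sum()), float(col[~in_shared].sum())

        n_sh, n_un = split(neat_pct)
        e_sh, e_un = split(extract_pct)
        rows.append((s, n_sh, n_un, e_sh, e_un))
    return pd.DataFrame(
        rows,
        columns=["sample", "neat_shared_pct", "neat_unique_pct",
                 "extract_shared_pct", "extract_unique_pct"],
    ).set_index("sample")


def series_share_profiles(
    annotated_pct: FeatureMatrix, standardize: bool = True
) -> pd.DataFrame:
    """Substances x homologous-series percent-share profiles for clustering.

    Percent abundance is summed over each assigned homologous series
    (unassigned features pool into an ``unassigned`` column), which
    averages out single-feature abundance noise and keeps the class-level
    compositional signal.  With ``standardize`` each series column is
    z-scored across substances so no single high-variance series dominates
    the distance; constant columns are dropped.
    """
    if annotated_pct.units != "percent":
        raise ValueError("series_share_profiles expects a percent-normalized matrix")
    sid = annotated_pct.meta["series_id"]
    key = sid.astype(object).where(sid.notna(), "unassigned")
    prof = annotated_pct.abundance.groupby(key).sum().T  # substances x series
    prof.columns = [f"series_{c}" for c in prof.columns]
    if standardize:
        sds = prof.std(axis=0, ddof=1)
        prof = prof.drop(columns=sds[sds == 0].index)
        prof = (prof - prof.mean(axis=0)) / prof.std(axis=0, ddof=1)
    return prof


def carbon_dbe_profile(annotated: FeatureMatrix) -> pd.DataFrame:
    """Carbon-number x DBE abundance profile per sample.

    Aggregates percent abundance over features sharing (#C, DBE); the
    standard hydrocarbon-class presentation for complex petroleum
    substances.  Unannotated features are reported as one row with
    ``n_C = -1, dbe = NaN``.
    """
    recs = []
    has_formula = annotated.meta["formula"].notna()
    for s in annotated.samples:
        col = annotated.abundance[s]
        grouped: dict[tuple, float] = {}
        for fid, f in annotated.meta.loc[has_formula, "formula"].items():
            key = (f.n_C, compute_dbe(f))
            grouped[key] = grouped.get(key, 0.0) + float(col[fid])
        for (nc, dbe), tot in sorted(grouped.items()):
            recs.append((s, nc, dbe, tot))
        un = float(col[~has_formula].sum())
        if un > 0:
            recs.append((s, -1, np.nan, un))
    return pd.DataFrame(recs, columns=["sample", "n_C", "dbe", "pct_abundance"])


def typical_constituent_report(
    annotated_pct: FeatureMatrix, constituent_formulas: list[MolecularFormula]
) -> pd.DataFrame:
    """Observed percent-abundance range per constituent formula.

    For each formula, sums percent abundance over matching features per
    sample and reports the min-max across samples; formulas never detected
    are flagged not-detected (``n.d.``).
    """
    rows = []
    for f in constituent_formulas:
        mask = annotated_pct.meta["formula"].map(lambda g: g == f).to_numpy()
        if not mask.any():
            rows.append((str(f), np.nan, np.nan, True))
            continue
        per_sample = annotated_pct.abundance.loc[mask].sum(axis=0)
        rows.append((str(f), float(per_sample.min()), float(per_sample.max()), False))
    return pd.DataFrame(
        rows, columns=["formula", "pct_min", "pct_max", "not_detected"]
    ).set_index("formula")
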