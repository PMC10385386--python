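"""Synthetic substance panels with known ground truth.

Generates the two kinds of raw data the pipeline consumes — nontarget
feature matrices with CH2-homologous-series structure, and plate-based
concentration-response readouts — from explicit generative models, exporting
every latent quantity (formula map, series map, planted EC10s, driver
features) so each downstream stage can be tested by parameter recovery.

The chemistry model: a panel of substances in two manufacturing categories,
each feature a member of a declared homologous series (base formula plus
k CH2 units), m/z the exact protonated mass, CCS affine in mass^(2/3)
within a series with 0.3% multiplicative jitter, abundances log-normal with
a decaying within-series envelope.  High-DBE (polycyclic-aromatic-like)
series are enriched by a constant factor in the second ("RO-like")
category, so the categories differ in aromatic content.

The bioassay model: cytotoxicity-like responses that decrease from the
100% vehicle level along a Hill curve whose EC50 is a planted log-linear
function of a weighted burden of driver-feature abundances, with
multiplicative log-normal noise, method-blank/DMSO/media control wells,
duplicate plates and intra-plate replicate substances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formula import MolecularFormula, compute_dbe
from .matrix import AnchorLibraryEntry, FeatureMatrix

# Fixed per-generator RNG stream offsets: adding a generator never perturbs
# the streams of existing ones.
_STREAM_FEATURES = 11
_STREAM_CCS = 12
_STREAM_PLATES = 21


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


_DEFAULT_BASES = (
    MolecularFormula(7, 16),    # n-alkanes, DBE 0
    MolecularFormula(6, 12),    # olefins/monocycloalkanes, DBE 1
    MolecularFormula(6, 6),     # alkylbenzenes, DBE 4
    MolecularFormula(9, 10),    # indanes, DBE 5
    MolecularFormula(10, 8),    # naphthalenes, DBE 7
    MolecularFormula(14, 10),   # anthracenes, DBE 10
    MolecularFormula(16, 10),   # pyrenes, DBE 12
    MolecularFormula(20, 12),   # 5-ring PACs, DBE 15
)


@dataclass
class PanelConfig:
    """Configuration of a synthetic substance panel.

    ``pac_enrichment_factor`` multiplies the abundances of high-DBE series
    (base DBE >= ``pac_dbe_threshold``) in the last category; it is the
    planted between-category compositional difference.
    """

    n_substances: int = 25
    n_categories: int = 2
    subcategory_sizes: tuple[int, ...] = (7, 6, 6, 6)
    n_series: int = len(_DEFAULT_BASES)
    series_base_formulas: tuple[MolecularFormula, ...] = _DEFAULT_BASES
    series_length: int = 12
    abundance_lognormal_mu_sigma: tuple[float, float] = (8.5, 1.2)
    pac_enrichment_factor: float = 4.0
    pac_dbe_threshold: float = 7.0
    # co-occurring heavy-PAC cluster: one extra short series whose members
    # rise and fall together across substances (a shared boiling-range /
    # source signature), the natural candidate driver set for bioactivity
    driver_series_base: MolecularFormula | None = MolecularFormula(22, 12)  # DBE 17
    driver_series_length: int = 6  # 7 members
    driver_factor_sigma: float = 1.0  # log-SD of the latent per-substance content
    driver_idio_sigma: float = 0.3  # within-cluster idiosyncratic log-SD
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.subcategory_sizes) != self.n_substances:
            raise ValueError(
                f"subcategory sizes {self.subcategory_sizes} must sum to "
                f"n_substances={self.n_substances}"
            )
        if self.pac_enrichment_factor < 1:
            raise ValueError("pac_enrichment_factor must be >= 1")
        if self.n_series != len(self.series_base_formulas):
            raise ValueError("n_series must equal len(series_base_formulas)")
        if self.series_length < 0:
            raise ValueError("series_length must be >= 0")

    def substance_table(self) -> pd.DataFrame:
        """Substance metadata: id, category, human-health subcategory."""
        subs, cats, subcats = [], [], []
        # subcategories split evenly across categories, in order
        per_cat = max(1, len(self.subcategory_sizes) // self.n_categories)
        i = 0
        for s_idx, size in enumerate(self.subcategory_sizes):
            cat = min(s_idx // per_cat, self.n_categories - 1)
            for _ in range(size):
                subs.append(f"S{i + 1:02d}")
                cats.append(f"CAT{cat + 1}")
                subcats.append(f"SUB{s_idx + 1}")
                i += 1
        return pd.DataFrame(
            {"category": cats, "subcategory": subcats}, index=pd.Index(subs, name="substance_id")
        )


@dataclass
class PanelTruth:
    """Ground truth exported with a synthetic feature matrix."""

    formula_map: dict[str, MolecularFormula]
    series_map: dict[str, int]
    series_bases: dict[int, MolecularFormula]
    substances: pd.DataFrame  # category / subcategory per substance
    high_dbe_series: set[int]
    driver_feature_ids: tuple[str, ...] = ()
    driver_factor: pd.Series | None = None  # latent heavy-PAC content


def generate_feature_matrix(config: PanelConfig) -> tuple[FeatureMatrix, PanelTruth]:
    """Generate a features x substances abundance matrix with known formulas.

    Deterministic for a fixed ``config.seed``.
    """
    rng_ab = _rng(config.seed, _STREAM_FEATURES)
    rng_ccs = _rng(config.seed, _STREAM_CCS)
    substances = config.substance_table()
    mu, sigma = config.abundance_lognormal_mu_sigma

    rows = []
    formula_map: dict[str, MolecularFormula] = {}
    series_map: dict[str, int] = {}
    high_dbe: set[int] = set()
    fid = 0
    bases: list[tuple[MolecularFormula, int]] = [
        (b, config.series_length) for b in config.series_base_formulas
    ]
    driver_sid = None
    if config.driver_series_base is not None:
        driver_sid = len(bases)
        bases.append((config.driver_series_base, config.driver_series_length))
    for s_idx, (base, length) in enumerate(bases):
        if compute_dbe(base) >= config.pac_dbe_threshold:
            high_dbe.add(s_idx)
        # CCS model: affine in mass^(2/3) within the series
        a = rng_ccs.uniform(20.0, 60.0)
        b = rng_ccs.uniform(2.6, 3.4)
        for k in range(length + 1):
            f = base.add_ch2(k)
            mass = f.monoisotopic_mass
            ccs = (a + b * mass ** (2 / 3)) * (1 + rng_ccs.normal(0.0, 0.003))
            feature_id = f"F{fid + 1:04d}"
            fid += 1
            rows.append((feature_id, f.mz_protonated(), ccs, s_idx, k))
            formula_map[feature_id] = f
            series_map[feature_id] = s_idx

    meta = pd.DataFrame(
        rows, columns=["feature_id", "mz", "ccs", "true_series", "k"]
    ).set_index("feature_id")

    n_feat = len(meta)
    n_sub = config.n_substances
    # within-series envelope: abundance decays with CH2 extensions
    envelope = np.exp(-0.12 * meta["k"].to_numpy())
    ab = rng_ab.lognormal(mu, sigma, size=(n_feat, n_sub)) * envelope[:, None]

    driver_ids: tuple[str, ...] = ()
    factor = None
    if driver_sid is not None:
        # cluster members co-vary through a shared latent content factor,
        # with only mild idiosyncratic noise on top
        in_cluster = (meta["true_series"] == driver_sid).to_numpy()
        factor_vals = rng_ab.lognormal(0.0, config.driver_factor_sigma, size=n_sub)
        idio = rng_ab.lognormal(mu, config.driver_idio_sigma, size=(in_cluster.sum(), n_sub))
        ab[in_cluster] = idio * factor_vals[None, :] * envelope[in_cluster, None]
        driver_ids = tuple(meta.index[in_cluster])
        factor = pd.Series(factor_vals, index=substances.index, name="driver_factor")

    enriched_cat = f"CAT{config.n_categories}"
    in_high = meta["true_series"].isin(high_dbe).to_numpy()
    is_enriched_sub = (substances["category"] == enriched_cat).to_numpy()
    ab[np.ix_(in_high, is_enriched_sub)] *= config.pac_enrichment_factor

    abundance = pd.DataFrame(ab, index=meta.index, columns=substances.index)
    fm = FeatureMatrix(meta[["mz", "ccs"]].copy(), abundance)
    truth = PanelTruth(
        formula_map=formula_map,
        series_map=series_map,
        series_bases={i: b for i, (b, _) in enumerate(bases)},
        substances=substances,
        high_dbe_series=high_dbe,
        driver_feature_ids=driver_ids,
        driver_factor=factor,
    )
    return fm, truth


def make_anchor_library(
    panel: FeatureMatrix, truth: PanelTruth
) -> list[AnchorLibraryEntry]:
    """Anchor library from each series' base member, with the generated
    feature's m/z and CCS as reference values."""
    entries = []
    for fid, s_idx in truth.series_map.items():
        if truth.formula_map[fid] == truth.series_bases[s_idx]:
            entries.append(
                AnchorLibraryEntry(
                    name=f"anchor_series{s_idx}",
                    formula=truth.formula_map[fid],
                    ref_mz=float(panel.meta.loc[fid, "mz"]),
                    ref_ccs=float(panel.meta.loc[fid, "ccs"]),
                )
            )
    return entries


# ---------------------------------------------------------------------------
# bioassay plates
# ---------------------------------------------------------------------------

#: Five-point serial dilution designs (µg/mL), by cell type.
NEURON_CONCENTRATIONS = (500.0, 50.0, 5.0, 0.5, 0.05)
DEFAULT_CONCENTRATIONS = (1000.0, 100.0, 10.0, 1.0, 0.1)

DEFAULT_CELL_TYPES = ("cardiomyocyte", "endothelial", "hepatocyte", "neuron", "huvec")


@dataclass
class PlateDesign:
    """Endpoints (cell type x phenotype) and their concentration series."""

    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    phenotypes_per_cell_type: int = 4
    n_blank_wells: int = 4
    n_control_wells: int = 4  # per role: dmso, media
    n_plates: int = 2  # inter-plate duplicates
    intra_plate_replicates: int = 2  # substances duplicated within each plate

    def endpoints(self) -> list[str]:
        return [
            f"{ct}:ph{p + 1}"
            for ct in self.cell_types
            for p in range(self.phenotypes_per_cell_type)
        ]

    def concentrations(self, endpoint: str) -> tuple[float, ...]:
        return (
            NEURON_CONCENTRATIONS
            if endpoint.startswith("neuron")
            else DEFAULT_CONCENTRATIONS
        )


@dataclass
class PlantedEffect:
    """Planted chemistry -> potency map.

    The driver burden of substance i is ``sum_j weights[j] * pct[j, i]``
    where pct is the driver feature's share of total abundance (percent).
    Burdens are standardized across the panel and mapped to
    ``log10 EC50 = ec50_log10_center - ec50_log10_span * z(burden)`` per
    endpoint, so high-burden substances are more potent (lower EC50).
    """

    driver_feature_ids: tuple[str, ...]
    weights: tuple[float, ...]
    ec50_log10_center: float = 1.5
    ec50_log10_span: float = 1.0
    endpoint_offsets_sd: float = 0.1  # per-endpoint log10 EC50 jitter
    hill_slope: float = 1.5
    bottom: float = 0.0
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if len(self.driver_feature_ids) != len(self.weights):
            raise ValueError("one weight per driver feature required")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def default_planted_effect(
    panel: FeatureMatrix, truth: PanelTruth, n_drivers: int | None = None, **kwargs
) -> PlantedEffect:
    """Drivers default to the panel's co-occurring heavy-PAC cluster; when
    the panel has none, the most abundant high-DBE features are used."""
    if truth.driver_feature_ids:
        drivers = truth.driver_feature_ids
        if n_drivers is not None:
            drivers = drivers[:n_drivers]
    else:
        in_high = panel.meta.index[
            [truth.series_map[f] in truth.high_dbe_series for f in panel.meta.index]
        ]
        totals = panel.abundance.loc[in_high].sum(axis=1).sort_values(ascending=False)
        drivers = tuple(totals.index[: (n_drivers or 7)])
    return PlantedEffect(tuple(drivers), tuple([1.0] * len(drivers)), **kwargs)


def hill_response(
    c: np.ndarray | float, ec50: float, slope: float, top: float = 100.0, bottom: float = 0.0
) -> np.ndarray | float:
    """Decreasing Hill curve: vehicle level ``top`` at c=0, plateau ``bottom``."""
    return bottom + (top - bottom) / (1.0 + (np.asarray(c, dtype=float) / ec50) ** slope)


def analytic_ec10(
    ec50: float, slope: float, top: float = 100.0, bottom: float = 0.0
) -> float:
    """Concentration where the Hill curve departs 10% from the vehicle level.

    Solves ``R(c) = top - 10``; infinite when the span cannot reach a 10%
    departure.
    """
    target = top - 10.0
    if target <= bottom:
        return np.inf
    return ec50 * ((top - target) / (target - bottom)) ** (1.0 / slope)


@dataclass
class SyntheticBioassay:
    """Raw plate tables plus the generating ground truth."""

    plates: pd.DataFrame  # long table, documented CSV dialect
    true_ec50: pd.DataFrame  # substances x endpoints, µg/mL
    true_ec10: pd.DataFrame  # substances x endpoints, µg/mL
    burden: pd.Series  # standardized driver burden per substance
    design: PlateDesign
    effect: PlantedEffect


def generate_bioassay_plates(
    panel: FeatureMatrix,
    effect: PlantedEffect,
    design: PlateDesign | None = None,
    seed: int = 0,
    blank_level: float = 1000.0,
) -> SyntheticBioassay:
    """Simulate raw plate readouts for every substance x endpoint.

    Raw values are instrument units with the method-blank wells centered at
    ``blank_level``; test-well raw values are ``blank_level x R(c)/100`` with
    multiplicative log-normal noise of coefficient of variation
    ``effect.noise_cv``.
    """
    design = design or PlateDesign()
    rng = _rng(seed, _STREAM_PLATES)
    missing = [f for f in effect.driver_feature_ids if f not in panel.meta.index]
    if missing:
        raise ValueError(f"driver features absent from panel: {missing}")

    pct = panel.abundance / panel.abundance.sum(axis=0) * 100.0
    w = pd.Series(effect.weights, index=list(effect.driver_feature_ids))
    burden_raw = pct.loc[w.index].mul(w, axis=0).sum(axis=0)
    z = (burden_raw - burden_raw.mean()) / burden_raw.std(ddof=1)

    endpoints = design.endpoints()
    ep_offset = {
        ep: rng.normal(0.0, effect.endpoint_offsets_sd) for ep in endpoints
    }
    substances = list(panel.samples)
    log_ec50 = pd.DataFrame(
        {
            ep: effect.ec50_log10_center - effect.ec50_log10_span * z + ep_offset[ep]
            for ep in endpoints
        },
        index=substances,
    )
    ec50 = 10.0 ** log_ec50
    ec10 = ec50.apply(
        lambda col: [
            analytic_ec10(v, effect.hill_slope, 100.0, effect.bottom) for v in col
        ]
    )
    ec10 = pd.DataFrame(ec10.to_dict(), index=substances)[endpoints]

    sigma = float(np.sqrt(np.log1p(effect.noise_cv**2)))

    def noisy(values: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return values
        return values * np.exp(rng.normal(0.0, sigma, size=np.shape(values)) - sigma**2 / 2)

    rows: list[tuple] = []
    replicated = substances[: design.intra_plate_replicates]
    for p in range(design.n_plates):
        plate_id = f"P{p + 1}"
        well = 0

        def add(substance, conc, ep, raw, role):
            nonlocal well
            well += 1
            rows.append((plate_id, f"W{well:04d}", substance, conc, ep, float(raw), role))

        for ep in endpoints:
            for _ in range(design.n_blank_wells):
                add("", 0.0, ep, noisy(np.array(blank_level)), "method_blank")
            for _ in range(design.n_control_wells):
                add("", 0.0, ep, noisy(np.array(blank_level)), "dmso")
                add("", 0.0, ep, noisy(np.array(blank_level)), "media")
            add("", 0.0, ep, noisy(np.array(blank_level * 0.05)), "positive_control")
            concs = np.array(design.concentrations(ep))
            for s in substances:
                reps = 2 if s in replicated else 1
                for _ in range(reps):
                    resp = hill_response(
                        concs, float(ec50.loc[s, ep]), effect.hill_slope,
                        100.0, effect.bottom,
                    )
                    raws = noisy(blank_level * resp / 100.0)
                    for c, r in zip(concs, raws):
                        add(s, float(c), ep, r, "test")

    plates = pd.DataFrame(
        rows,
        columns=[
            "plate_id", "well", "substance_id", "concentration_ug_per_ml",
            "endpoint", "raw_value", "well_role",
        ],
    )
    return SyntheticBioassay(plates, ec50, ec10, z, design, effect)
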