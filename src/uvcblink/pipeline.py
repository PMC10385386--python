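"""End-to-end orchestration of the grouping/association workflow.

Runs chemistry characterization -> bioassay POD derivation -> ToxPi scoring
-> hierarchical grouping -> ridge association from a single configuration,
writing every stage's tables plus a manifest (seeds, thresholds, input
hashes) to a run directory.  In synthetic mode the inputs are generated by
:mod:`uvcblink.synthetic`; in file mode they are read from the documented
CSV dialects.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, bioassay, chem_features, grouping, synthetic, toxpi
from .matrix import FeatureMatrix, read_anchor_library

ALL_STAGES = ("chem", "bioassay", "toxpi", "cluster", "assoc")


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run.

    Every workflow threshold is a named key defaulting to the standard
    value: 5000-count abundance filter, +-5 ppm / +-1% CCS anchor
    tolerances, >1% predictor threshold, 10% POD departure, 0.8 QC
    correlation, log10(lambda) in [-1, 6] step 0.1, 1000 permutations.
    """

    outdir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # inputs: synthetic mode when feature_csv is None
    feature_csv: str | None = None
    anchor_csv: str | None = None
    plate_csv: str | None = None
    # synthetic panel
    n_substances: int = 25
    subcategory_sizes: tuple[int, ...] = (7, 6, 6, 6)
    pac_enrichment_factor: float = 4.0
    n_drivers: int = 7
    noise_cv: float = 0.05
    phenotypes_per_cell_type: int = 4
    # thresholds
    abundance_filter: float = 5000.0
    ppm_tol: float = 5.0
    ccs_tol_pct: float = 1.0
    predictor_min_pct: float = 1.0
    pod_departure: float = 10.0
    qc_r_threshold: float = 0.8
    # association
    log_lambda_min: float = -1.0
    log_lambda_max: float = 6.0
    log_lambda_step: float = 0.1
    n_perm: int = 1000
    perm_reselect_lambda: bool = True
    # grouping
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "complete"
    n_subgroups: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("feature_csv", "anchor_csv", "plate_csv"):
            val = getattr(cfg, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{key}: no such file {val}")
        if cfg.log_lambda_max < cfg.log_lambda_min:
            raise ValueError("empty lambda grid")
        return cfg

    def lambda_grid(self) -> np.ndarray:
        return 10.0 ** np.round(
            np.arange(self.log_lambda_min, self.log_lambda_max + 1e-9, self.log_lambda_step), 10
        )


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    A stage failure aborts with a stage-tagged message; outputs written by
    earlier stages are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages_run": [],
        "input_hashes": {},
        "conventions": {
            "ion_mode": "[M+H]+",
            "kmd": "round(KM) - KM",
            "sd": "sample (n-1)",
            "censoring": f"{bioassay.CENSOR_FACTOR} x highest tested concentration",
        },
    }

    stage = "setup"
    try:
        # ---- inputs -------------------------------------------------------
        synthetic_mode = config.feature_csv is None
        if synthetic_mode:
            panel_cfg = synthetic.PanelConfig(
                n_substances=config.n_substances,
                subcategory_sizes=tuple(config.subcategory_sizes),
                pac_enrichment_factor=config.pac_enrichment_factor,
                seed=config.seed,
            )
            panel, truth = synthetic.generate_feature_matrix(panel_cfg)
            anchors = synthetic.make_anchor_library(panel, truth)
            effect = synthetic.default_planted_effect(
                panel, truth, n_drivers=config.n_drivers, noise_cv=config.noise_cv
            )
            design = synthetic.PlateDesign(
                phenotypes_per_cell_type=config.phenotypes_per_cell_type
            )
            bio = synthetic.generate_bioassay_plates(panel, effect, design, seed=config.seed)
            plates = bio.plates
            substances = truth.substances
            panel.to_csv(out / "input_features.csv")
            plates.to_csv(out / "input_plates.csv", index=False)
            (out / "ground_truth.json").write_text(json.dumps({
                "driver_features": list(effect.driver_feature_ids),
                "formula_map": {k: str(v) for k, v in truth.formula_map.items()},
                "true_ec10": {c: bio.true_ec10[c].to_dict() for c in bio.true_ec10},
            }, indent=1))
        else:
            panel = FeatureMatrix.from_csv(config.feature_csv)
            anchors = read_anchor_library(config.anchor_csv)
            plates = pd.read_csv(config.plate_csv).fillna({"substance_id": ""})
            substances = None
            for key in ("feature_csv", "anchor_csv", "plate_csv"):
                manifest["input_hashes"][key] = _sha(Path(getattr(config, key)))

        results: dict = {}

        # ---- chemistry ----------------------------------------------------
        if "chem" in config.stages:
            stage = "chem"
            filtered = chem_features.filter_by_abundance(panel, config.abundance_filter)
            matches = chem_features.match_anchors(
                filtered, anchors, config.ppm_tol, config.ccs_tol_pct
            )
            annotated, series_report = chem_features.assign_series_and_formulas(
                filtered, matches, ppm_tol=config.ppm_tol
            )
            pct = chem_features.percent_total_abundance(annotated)
            comp = chem_features.summarize_composition(pct)
            profile = chem_features.carbon_dbe_profile(pct)
            pct.to_csv(out / "chem_percent_matrix.csv")
            comp.bin_abundance.to_csv(out / "chem_bins.csv")
            profile.to_csv(out / "chem_carbon_dbe.csv", index=False)
            results["pct"] = pct
            manifest["stages_run"].append("chem")
            manifest["chem"] = {
                "n_features_filtered": len(filtered.feature_ids),
                "n_anchored": len(matches),
                "n_with_formula": series_report.n_features_with_formula,
                "rejected_series": series_report.rejected_series,
            }

        # ---- bioassay -----------------------------------------------------
        if "bioassay" in config.stages:
            stage = "bioassay"
            normalized = bioassay.normalize_to_method_blank(plates)
            qc_veh = bioassay.qc_vehicle_effect(normalized)
            pods, _ = bioassay.pods_from_plates(plates)
            pods.table.to_csv(out / "pod_table.csv", index=False)
            (out / "qc_report.json").write_text(json.dumps({
                "vehicle_effect": {"passed": bool(qc_veh.passed), "reason": qc_veh.reason},
            }, indent=1))
            results["pods"] = pods
            manifest["stages_run"].append("bioassay")

        # ---- toxpi --------------------------------------------------------
        if "toxpi" in config.stages and "pods" in results:
            stage = "toxpi"
            per_ct = toxpi.celltype_toxpi(results["pods"])
            ct_scores = pd.DataFrame({ct: p.scores for ct, p in per_ct.items()})
            overall = toxpi.overall_toxpi(ct_scores)
            slice_frames = [p.to_frame().assign(cell_type=ct) for ct, p in per_ct.items()]
            pd.concat(slice_frames).to_csv(out / "toxpi_slices.csv", index=False)
            scores = ct_scores.copy()
            scores["overall"] = overall.scores
            scores.to_csv(out / "toxpi_scores.csv", index_label="substance_id")
            results["celltype_profiles"] = per_ct
            results["scores"] = scores
            manifest["stages_run"].append("toxpi")

        # ---- grouping -----------------------------------------------------
        if "cluster" in config.stages and "pct" in results:
            stage = "cluster"
            chem_profiles = chem_features.series_share_profiles(results["pct"])
            dend = grouping.cluster_substances(
                chem_profiles, config.cluster_metric, config.cluster_linkage
            )
            labels = grouping.cut_to_subgroups(dend, min(config.n_subgroups, len(chem_profiles)))
            dend.to_frame().to_csv(out / "chem_linkage.csv", index=False)
            labels.to_csv(out / "chem_clusters.csv")
            (out / "chem_dendrogram.nwk").write_text(dend.to_newick())
            if substances is not None:
                ari, purity = grouping.concordance_with_categories(
                    labels, substances["subcategory"]
                )
                n_cat = substances["category"].nunique()
                cat_labels = grouping.cut_to_subgroups(dend, n_cat)
                cat_ari, _ = grouping.concordance_with_categories(
                    cat_labels, substances["category"]
                )
                manifest["cluster"] = {
                    "chem_ari_vs_subcategory": ari,
                    "chem_ari_vs_category": cat_ari,
                }
            if "scores" in results:
                bio_profiles = pd.concat(
                    [p.slice_values for p in results["celltype_profiles"].values()], axis=1
                )
                bdend = grouping.cluster_substances(
                    bio_profiles, config.cluster_metric, config.cluster_linkage
                )
                bdend.to_frame().to_csv(out / "bio_linkage.csv", index=False)
            manifest["stages_run"].append("cluster")

        # ---- association --------------------------------------------------
        if "assoc" in config.stages and "pct" in results and "scores" in results:
            stage = "assoc"
            X = association.build_predictor_matrix(results["pct"], config.predictor_min_pct)
            Y = results["scores"].loc[X.index]
            observed, perm = association.permutation_test(
                X, Y, config.lambda_grid(), n_perm=config.n_perm,
                seed=config.seed, reselect_lambda=config.perm_reselect_lambda,
            )
            infl = association.influential_features(X, Y)
            observed.B.to_csv(out / "ridge_coefficients.csv")
            observed.cv_predictions.to_csv(out / "cv_predictions.csv")
            perm.table.to_csv(out / "association_stats.csv")
            infl.to_csv(out / "influential_features.csv")
            reverse = association.reverse_prediction(X, Y, config.lambda_grid())
            reverse.r.to_csv(out / "reverse_prediction_r.csv")
            manifest["stages_run"].append("assoc")
            manifest["assoc"] = {
                "lambda_selected": observed.lambda_selected,
                "n_predictors": X.shape[1],
                "q_overall": float(perm.table.loc["overall", "q"]) if "overall" in perm.table.index else None,
            }
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
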