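"""Chemistry -> bioactivity association by tuned multivariate ridge.

Builds the >1% predictor matrix, scores substances via the full POD/ToxPi
path, then runs leave-one-out-tuned ridge with a permutation z-test on the
cross-validated prediction correlations, and ranks influential features.
"""

import pandas as pd

from uvcblink import association, bioassay, chem_features, synthetic, toxpi

config = synthetic.PanelConfig(seed=1, series_length=33)
panel, truth = synthetic.generate_feature_matrix(config)
pct = chem_features.percent_total_abundance(
    chem_features.filter_by_abundance(panel, 5000.0)
)
X = association.build_predictor_matrix(pct, min_pct=1.0)
print(f"predictors: {X.shape[0]} substances x {X.shape[1]} features (> 1%)")

# bioactivity scores from simulated plates
effect = synthetic.default_planted_effect(panel, truth, noise_cv=0.05)
bio = synthetic.generate_bioassay_plates(
    panel, effect, synthetic.PlateDesign(phenotypes_per_cell_type=2), seed=1
)
pods, _ = bioassay.pods_from_plates(bio.plates)
profiles = toxpi.celltype_toxpi(pods)
Y = pd.DataFrame({ct: p.scores for ct, p in profiles.items()})
Y["overall"] = toxpi.overall_toxpi(Y[list(profiles)]).scores
Y = Y.loc[X.index]

observed, perm = association.permutation_test(X, Y, n_perm=1000, seed=1)
print(f"\nselected lambda: {observed.lambda_selected:.3g}")
print("\npermutation test per response:")
print(perm.table[["r", "z", "p", "q"]].round(4))

influential = association.influential_features(X, Y)
print("\ntop features by |r| with the overall score:")
top = influential.head(10)[["overall"]].round(3)
top["is_planted_driver"] = top.index.isin(effect.driver_feature_ids)
print(top)
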