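"""Nontarget chemical characterization of a synthetic substance panel.

Walks the chemistry stage end to end: abundance filtering, anchor matching
against a known-constituent library, Kendrick-series assignment with
formula propagation, percent-abundance normalization and composition
bookkeeping (abundance bins, 80%-coverage flag, carbon x DBE profile).
"""

from uvcblink import chem_features, synthetic

# a 25-substance panel with known ground-truth formulas
config = synthetic.PanelConfig(seed=1)
panel, truth = synthetic.generate_feature_matrix(config)
print(f"panel: {len(panel.feature_ids)} features x {len(panel.samples)} substances")

# 1. drop features never reaching the minimum abundance
filtered = chem_features.filter_by_abundance(panel, threshold=5000.0)
print(f"after 5000-count filter: {len(filtered.feature_ids)} features")

# 2. match against the anchor library (5 ppm m/z, 1% CCS)
library = synthetic.make_anchor_library(panel, truth)
matches = chem_features.match_anchors(filtered, library)
print(f"anchored features: {len(matches)}")

# 3. homologous-series assignment + formula propagation
annotated, report = chem_features.assign_series_and_formulas(filtered, matches)
print(
    f"series: {report.n_series} total, {len(report.anchored_series)} anchored, "
    f"{len(report.rejected_series)} rejected by CCS monotonicity; "
    f"{report.n_features_with_formula} features carry a formula"
)

# 4. percent of total abundance and composition summary
pct = chem_features.percent_total_abundance(annotated)
comp = chem_features.summarize_composition(pct)
print("\nabundance carried per bin (first 3 substances):")
print(comp.bin_abundance.head(3).round(2))
print("\nsubstances meeting the 80% characterization rule:",
      int(comp.meets_echa_80.sum()), "of", len(comp.meets_echa_80))

# 5. carbon-number x DBE class profile of the first substance
profile = chem_features.carbon_dbe_profile(pct)
first = profile[profile["sample"] == pct.samples[0]]
print(f"\ntop classes of {pct.samples[0]}:")
print(first.sort_values("pct_abundance", ascending=False).head(5).to_string(index=False))
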