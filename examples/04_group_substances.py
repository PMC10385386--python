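"""Hierarchical grouping of substances on chemical class profiles.

Clusters substances on standardized homologous-series share profiles,
exports the dendrogram as Newick, cuts it into subgroups and scores
concordance with the panel's planted categories.
"""

from uvcblink import chem_features, grouping, synthetic

config = synthetic.PanelConfig(seed=1, series_length=33)
panel, truth = synthetic.generate_feature_matrix(config)
filtered = chem_features.filter_by_abundance(panel, 5000.0)
matches = chem_features.match_anchors(filtered, synthetic.make_anchor_library(panel, truth))
annotated, _ = chem_features.assign_series_and_formulas(filtered, matches)
pct = chem_features.percent_total_abundance(annotated)

profiles = chem_features.series_share_profiles(pct)
print(f"clustering {profiles.shape[0]} substances on {profiles.shape[1]} series shares")

dend = grouping.cluster_substances(profiles)  # Euclidean, complete linkage
print("leaf order:", " ".join(dend.leaf_order()[:10]), "...")
print("newick (truncated):", dend.to_newick()[:80], "...")

labels = grouping.cut_to_subgroups(dend, 2)
ari, purity = grouping.concordance_with_categories(labels, truth.substances["category"])
print(f"\nk=2 cut vs planted categories: ARI = {ari:.3f}")
print("cluster purity:")
print(purity.round(2))
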