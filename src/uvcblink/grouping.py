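"""Unsupervised hierarchical grouping of substances.

Substances are clustered on their chemical percent-abundance profiles or
their bioactivity (ToxPi slice) profiles by agglomerative clustering —
Euclidean distance with complete linkage by default, the defaults of the R
``hclust``-based workflow this mirrors.  Concordance between the resulting
data-driven groups and assigned manufacturing categories or human-health
subcategories is quantified with the adjusted Rand index and per-category
purity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "Dendrogram",
    "cluster_substances",
    "cut_to_subgroups",
    "concordance_with_categories",
]


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray  # (n-1) x 4 scipy format
    labels: list[str]
    metric: str
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["child_a", "child_b", "height", "n_members"]
        )


def cluster_substances(
    profiles: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of substances (rows) on profile columns.

    Deterministic given the input row order and scipy's tie rule.  With the
    correlation metric, constant rows have undefined distances and raise.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two substances to cluster")
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles contain missing values; impute before clustering")
    if metric == "correlation" and (np.ptp(X, axis=1) == 0).any():
        raise ValueError(
            "constant profile rows make correlation distance undefined; "
            "use metric='euclidean'"
        )
    dist = pdist(X, metric=metric)
    Z = hierarchy.linkage(dist, method=method)
    return Dendrogram(Z, list(profiles.index), metric, method)


def cut_to_subgroups(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut the tree into ``k`` flat clusters; labels are 1..k."""
    if not 1 <= k <= dendrogram.n_leaves:
        raise ValueError(f"k must be in [1, {dendrogram.n_leaves}]")
    labels = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=dendrogram.labels, name="cluster")


def concordance_with_categories(
    cluster_labels: pd.Series, assigned: pd.Series
) -> tuple[float, pd.Series]:
    """Agreement between data-driven clusters and assigned categories.

    Returns the adjusted Rand index (1 = identical partitions, ~0 = chance)
    and per-assigned-category purity: the fraction of each category's
    substances that fall in that category's modal cluster.
    """
    assigned = assigned.loc[cluster_labels.index]
    ari = adjusted_rand_score(assigned.to_numpy(), cluster_labels.to_numpy())
    purity = {}
    for cat, idx in assigned.groupby(assigned).groups.items():
        counts = cluster_labels.loc[idx].value_counts()
        purity[cat] = counts.iloc[0] / counts.sum()
    return float(ari), pd.Series(purity, name="purity")
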