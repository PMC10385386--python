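"""ToxPi potency scoring: POD scaling, slice aggregation, overall scores.

Each POD is scaled onto [0, 1] relative to the most and least potent values
observed for that endpoint across the analyzed substances,

    value = 1 - (log10 POD - log10 PODmin) / (log10 PODmax - log10 PODmin),

so the most bioactive substance (lowest POD) scores 1 and the least scores
0.  Phenotype slices are averaged with equal weight into a per-cell-type
score; cell-type scores are then themselves treated as slices (log-scaled
and min-max re-scaled by default) and averaged into an overall score.
Censored PODs participate at their censoring value, which places them at
the least-bioactive end of the scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioassay import PODTable

__all__ = ["toxpi_value", "celltype_toxpi", "overall_toxpi", "ToxPiProfiles"]


def toxpi_value(pod: float, pod_min: float, pod_max: float) -> float:
    """Scale one POD onto [0, 1]; 1 at PODmin (most potent), 0 at PODmax.

    Degenerate case ``pod_min == pod_max`` (e.g. an endpoint where every
    substance is censored) returns 0 for all substances.
    """
    if pod_min <= 0:
        raise ValueError("pod_min must be positive")
    if pod_min == pod_max:
        return 0.0
    if not (pod_min <= pod <= pod_max):
        raise ValueError(f"pod {pod} outside [pod_min={pod_min}, pod_max={pod_max}]")
    return 1.0 - (np.log10(pod) - np.log10(pod_min)) / (
        np.log10(pod_max) - np.log10(pod_min)
    )


@dataclass
class ToxPiProfiles:
    """Slice values, weights and aggregate scores for a set of substances.

    ``slice_values`` is substances x slices with entries in [0, 1];
    ``weights`` are non-negative and sum to 1; ``scores`` is the weighted
    mean per substance, also in [0, 1].
    """

    slice_values: pd.DataFrame
    weights: pd.Series
    scores: pd.Series

    def __post_init__(self) -> None:
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    @classmethod
    def from_slices(cls, slice_values: pd.DataFrame, weights: pd.Series | None = None) -> "ToxPiProfiles":
        if weights is None:
            weights = pd.Series(
                1.0 / slice_values.shape[1], index=slice_values.columns
            )
        scores = slice_values.mul(weights, axis=1).sum(axis=1)
        return cls(slice_values, weights, scores)

    def to_frame(self) -> pd.DataFrame:
        """Long CSV-ready form: substance, slice, value, weight, score."""
        long = self.slice_values.stack().rename("value").reset_index()
        long.columns = ["substance_id", "slice", "value"]
        long["weight"] = long["slice"].map(self.weights)
        long["score"] = long["substance_id"].map(self.scores)
        return long


def _default_celltype_of(endpoint: str) -> str:
    return endpoint.split(":")[0]


def celltype_toxpi(
    pods: PODTable,
    celltype_of=_default_celltype_of,
    groups: pd.Series | None = None,
) -> dict[str, ToxPiProfiles]:
    """Per-cell-type ToxPi profiles, one equally weighted slice per phenotype.

    PODmin/PODmax are computed per endpoint over the scored substance set —
    over all substances by default, or within each group when ``groups``
    maps substances to categories (category-relative profiles).
    """
    wide = pods.wide()
    profiles: dict[str, ToxPiProfiles] = {}
    cell_of = {ep: celltype_of(ep) for ep in wide.columns}
    for ct in sorted(set(cell_of.values())):
        eps = [ep for ep in wide.columns if cell_of[ep] == ct]
        values = pd.DataFrame(index=wide.index, columns=eps, dtype=float)
        for ep in eps:
            col = wide[ep]
            if groups is None:
                scopes = [col.index]
            else:
                scopes = [col.index[groups.loc[col.index] == g] for g in groups.unique()]
            for idx in scopes:
                if len(idx) == 0:
                    continue
                pmin, pmax = float(col[idx].min()), float(col[idx].max())
                values.loc[idx, ep] = [toxpi_value(p, pmin, pmax) for p in col[idx]]
        profiles[ct] = ToxPiProfiles.from_slices(values)
    return profiles


def overall_toxpi(
    celltype_scores: pd.DataFrame, rescale: bool = True
) -> ToxPiProfiles:
    """Aggregate cell-type scores (substances x cell types) into one score.

    With ``rescale`` (default), each cell-type slice is log10 min-max scaled
    across substances so the highest score maps to 1 and the lowest to 0;
    zero scores map to 0 directly (log undefined; zero means no observed
    bioactivity).  Degenerate slices (constant, or a single substance)
    pass through unscaled.
    """
    if celltype_scores.shape[1] < 1:
        raise ValueError("need at least one cell type")
    values = celltype_scores.astype(float).copy()
    if rescale and len(values) > 1:
        for ct in values.columns:
            col = values[ct]
            pos = col[col > 0]
            if len(pos) < 2 or pos.min() == pos.max():
                continue
            lo, hi = np.log10(pos.min()), np.log10(pos.max())
            scaled = (np.log10(col.where(col > 0)) - lo) / (hi - lo)
            values[ct] = scaled.clip(0.0, 1.0).fillna(0.0)
    return ToxPiProfiles.from_slices(values)
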