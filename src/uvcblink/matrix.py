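"""Feature-matrix container shared by the chemistry modules.

A :class:`FeatureMatrix` holds the per-feature descriptors (m/z, CCS) and the
features x samples abundance table produced by nontarget IMS-MS processing.
Annotations (molecular formula, homologous-series id) are attached in place
by the characterization steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formula import MolecularFormula


@dataclass
class FeatureMatrix:
    """Features x samples abundance table with per-feature m/z and CCS.

    Attributes
    ----------
    meta : pandas.DataFrame
        Indexed by ``feature_id``; columns ``mz`` (Th) and ``ccs``
        (squared angstroms, drift-tube CCS in N2), plus optional
        ``formula`` (:class:`MolecularFormula` or None) and ``series_id``.
    abundance : pandas.DataFrame
        Indexed by ``feature_id`` (same order as ``meta``), one column per
        sample; finite, non-negative values.
    """

    meta: pd.DataFrame
    abundance: pd.DataFrame
    units: str = "counts"  # "counts" or "percent"

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.abundance.index):
            raise ValueError("meta and abundance must share the feature_id index")
        if self.meta.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if (self.meta["mz"] <= 0).any() or (self.meta["ccs"] <= 0).any():
            raise ValueError("m/z and CCS must be positive")
        vals = self.abundance.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("abundances must be finite and non-negative")
        if "formula" not in self.meta.columns:
            self.meta["formula"] = None
        if "series_id" not in self.meta.columns:
            self.meta["series_id"] = pd.array([pd.NA] * len(self.meta), dtype="Int64")

    # -- convenience -------------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.meta.index

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.meta.copy(), self.abundance.copy(), self.units)

    def subset(self, feature_ids) -> "FeatureMatrix":
        return FeatureMatrix(
            self.meta.loc[feature_ids].copy(),
            self.abundance.loc[feature_ids].copy(),
            self.units,
        )

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the documented CSV dialect: feature_id, mz, ccs, formula,
        series_id, then one ``abundance_<sample>`` column per sample."""
        out = self.meta.copy()
        out["formula"] = [str(f) if f is not None else "" for f in out["formula"]]
        ab = self.abundance.add_prefix("abundance_")
        pd.concat([out, ab], axis=1).to_csv(path, index_label="feature_id")

    @classmethod
    def from_csv(cls, path: str | Path, units: str = "counts") -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="feature_id")
        ab_cols = [c for c in df.columns if c.startswith("abundance_")]
        abundance = df[ab_cols].rename(columns=lambda c: c[len("abundance_"):])
        meta_cols = [c for c in df.columns if not c.startswith("abundance_")]
        meta = df[meta_cols].copy()
        if "formula" in meta.columns:
            meta["formula"] = [
                MolecularFormula.parse(s) if isinstance(s, str) and s else None
                for s in meta["formula"]
            ]
        if "series_id" in meta.columns:
            meta["series_id"] = meta["series_id"].astype("Int64")
        return cls(meta, abundance, units)


@dataclass(frozen=True)
class AnchorLibraryEntry:
    """Known constituent used to anchor nontarget features: name, formula,
    reference m/z (of the detected ion) and reference CCS."""

    name: str
    formula: MolecularFormula
    ref_mz: float
    ref_ccs: float

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            object.__setattr__(self, "formula", MolecularFormula.parse(self.formula))
        if self.ref_mz <= 0 or self.ref_ccs <= 0:
            raise ValueError("reference m/z and CCS must be positive")


def read_anchor_library(path: str | Path) -> list[AnchorLibraryEntry]:
    df = pd.read_csv(path)
    return [
        AnchorLibraryEntry(
            row["name"],
            MolecularFormula.parse(row["formula"]),
            float(row["ref_mz"]),
            float(row["ref_ccs"]),
        )
        for _, row in df.iterrows()
    ]


def write_anchor_library(entries: list[AnchorLibraryEntry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [e.name for e in entries],
            "formula": [str(e.formula) for e in entries],
            "ref_mz": [e.ref_mz for e in entries],
            "ref_ccs": [e.ref_ccs for e in entries],
        }
    ).to_csv(path, index=False)
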