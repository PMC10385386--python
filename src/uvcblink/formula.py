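"""Molecular formulas, exact masses, Kendrick mass defects and DBE.

Hydrocarbon-centric formula arithmetic used throughout the nontarget
feature-characterization workflow.  Features are assumed to be CHN(OS)
species detected in positive mode as protonated molecules ``[M+H]+`` (the
default ion convention; charge-exchange ``M+.`` is available via
``proton_offset=0``).
"""

from __future__ import annotations

from dataclasses import dataclass

# CODATA / IUPAC 2021 monoisotopic masses (u)
MASS_C = 12.0
MASS_H = 1.00782503207
MASS_N = 14.0030740048
MASS_O = 15.9949146196
MASS_S = 31.97207100
MASS_PROTON = 1.007276466621

#: Exact mass of one CH2 repeat unit, used for formula/mass arithmetic.
CH2_MASS = MASS_C + 2 * MASS_H  # 14.0156500641...

#: Conventional Kendrick base for CH2: the repeat-unit mass at the precision
#: universally quoted in the petroleomics literature.
KENDRICK_CH2 = 14.01565


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Element counts of a CHN(OS) molecular formula.

    Parameters
    ----------
    n_C, n_H : int
        Carbon and hydrogen counts; ``n_C >= 1`` for any assigned
        hydrocarbon feature.
    n_N, n_O, n_S : int
        Heteroatom counts, default 0.
    """

    n_C: int
    n_H: int
    n_N: int = 0
    n_O: int = 0
    n_S: int = 0

    def __post_init__(self) -> None:
        for name in ("n_C", "n_H", "n_N", "n_O", "n_S"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def monoisotopic_mass(self) -> float:
        """Exact neutral monoisotopic mass in u."""
        return (
            self.n_C * MASS_C
            + self.n_H * MASS_H
            + self.n_N * MASS_N
            + self.n_O * MASS_O
            + self.n_S * MASS_S
        )

    def mz_protonated(self) -> float:
        """m/z of the singly protonated molecule [M+H]+."""
        return self.monoisotopic_mass + MASS_PROTON

    def add_ch2(self, k: int = 1) -> "MolecularFormula":
        """Return the formula extended by ``k`` CH2 units (k may be negative)."""
        return MolecularFormula(
            self.n_C + k, self.n_H + 2 * k, self.n_N, self.n_O, self.n_S
        )

    def __str__(self) -> str:
        parts = []
        for sym, n in (("C", self.n_C), ("H", self.n_H), ("N", self.n_N),
                       ("O", self.n_O), ("S", self.n_S)):
            if n == 1:
                parts.append(sym)
            elif n > 1:
                parts.append(f"{sym}{n}")
        return "".join(parts) or "∅"

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-order formula string such as ``C10H8`` or ``C9H7N``."""
        import re

        counts = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0}
        pos = 0
        for m in re.finditer(r"([CHNOS])(\d*)", text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            counts[m.group(1)] += int(m.group(2) or 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts["C"], counts["H"], counts["N"], counts["O"], counts["S"])


def compute_dbe(f: MolecularFormula) -> float:
    """Double bond equivalence: rings plus multiple bonds of the formula.

    ``DBE = #C + 1 - #H/2 + #N/2``.  Oxygen and sulfur (divalent) do not
    contribute.  Integer for even-electron CHN formulas with even #H + #N,
    half-integer for radicals.
    """
    return f.n_C + 1 - f.n_H / 2 + f.n_N / 2


def kendrick_mass_defect(mz: float, base_mass: float = KENDRICK_CH2) -> tuple[float, float]:
    """Kendrick mass and mass defect for the CH2 repeat unit.

    The IUPAC mass scale is rescaled so the repeat unit has integer mass
    (CH2 -> 14); members of an exact CH2 homologous series then share a
    common mass defect.  Returns ``(kendrick_mass, kmd)`` with the
    petroleomics convention ``kmd = round(kendrick_mass) - kendrick_mass``.
    """
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    nominal_base = round(base_mass)
    kendrick_mass = mz * (nominal_base / base_mass)
    kmd = round(kendrick_mass) - kendrick_mass
    return kendrick_mass, kmd
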