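import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uvcblink.formula import (
    CH2_MASS,
    KENDRICK_CH2,
    MASS_PROTON,
    MolecularFormula,
    compute_dbe,
    kendrick_mass_defect,
)


def test_dbe_known_values():
    assert compute_dbe(MolecularFormula.parse("C10H8")) == 7
    assert compute_dbe(MolecularFormula.parse("CH4")) == 0
    assert compute_dbe(MolecularFormula.parse("C10H12")) == 5


def test_dbe_nitrogen_contribution():
    # pyridine C5H5N: one ring + three double bonds
    assert compute_dbe(MolecularFormula(n_C=5, n_H=5, n_N=1)) == 4


def test_dbe_oxygen_sulfur_neutral():
    base = compute_dbe(MolecularFormula.parse("C10H8"))
    assert compute_dbe(MolecularFormula(n_C=10, n_H=8, n_O=2, n_S=1)) == base


def test_parse_roundtrip():
    f = MolecularFormula.parse("C12H10N2O1S1")
    assert (f.n_C, f.n_H, f.n_N, f.n_O, f.n_S) == (12, 10, 2, 1, 1)
    assert MolecularFormula.parse(str(f)) == f


def test_monoisotopic_mass_naphthalene():
    f = MolecularFormula.parse("C10H8")
    # 10 x 12 + 8 x 1.00782503
    assert f.monoisotopic_mass == pytest.approx(128.062600, abs=1e-5)
    assert f.mz_protonated() == pytest.approx(f.monoisotopic_mass + MASS_PROTON)


def test_add_ch2_mass_increment():
    f = MolecularFormula.parse("C10H8")
    g = f.add_ch2(3)
    assert (g.n_C, g.n_H) == (13, 14)
    assert g.monoisotopic_mass - f.monoisotopic_mass == pytest.approx(3 * CH2_MASS)


def test_ch2_homologue_preserves_dbe():
    f = MolecularFormula.parse("C10H8")
    assert compute_dbe(f.add_ch2(5)) == compute_dbe(f)


def test_kendrick_base_maps_to_integer():
    km, kmd = kendrick_mass_defect(KENDRICK_CH2)
    assert km == pytest.approx(14.0)
    assert kmd == pytest.approx(0.0, abs=1e-12)


def test_kmd_invariant_along_ch2_series():
    f = MolecularFormula.parse("C10H8")
    kmds = [kendrick_mass_defect(f.add_ch2(k).monoisotopic_mass)[1] for k in range(8)]
    assert np.ptp(kmds) < 5e-4  # exact-CH2 vs nominal base drift stays tiny


def test_kmd_separates_dbe_classes():
    a = kendrick_mass_defect(MolecularFormula.parse("C10H8").monoisotopic_mass)[1]
    b = kendrick_mass_defect(MolecularFormula.parse("C10H22").monoisotopic_mass)[1]
    assert abs(a - b) > 0.01


@settings(max_examples=100, deadline=None)
@given(
    n_c=st.integers(min_value=1, max_value=60),
    n_n=st.integers(min_value=0, max_value=4),
    dbe=st.integers(min_value=0, max_value=20),
)
def test_dbe_inverts_hydrogen_count(n_c, n_n, dbe):
    # construct H from the definition, then recover the DBE
    h2 = 2 * (n_c + 1) + n_n - 2 * dbe  # H = 2C + 2 + N - 2*DBE
    if h2 < 0:
        return
    f = MolecularFormula(n_C=n_c, n_H=h2, n_N=n_n)
    assert compute_dbe(f) == dbe
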