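"""Composition arithmetic, masses and isotope envelopes.

pyteomics (an independent implementation of peptide composition/mass
arithmetic) and a brute-force multinomial enumeration serve as oracles.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as ptmass

from isoxlink.chem import (
    AMMONIA,
    ISOTOPES,
    PROTON_MASS,
    WATER,
    ChemError,
    ElementalComposition,
    average_mass,
    isotope_distribution,
    monoisotopic_mass,
    mz_from_mass,
    peptide_composition,
    xlink_modification_composition,
)

#: The seven single-lysine TG2 donor peptides and the printed formulas of the
#: crosslink modifications they define (peptide composition minus NH3).
DONOR_FORMULAS = {
    "FLKNAGR": "C36H57N11O9",
    "WKNHGCQR": "C43H62N16O11S",
    "ISTKSVGR": "C35H63N11O12",
    "LAEKEETGMAMR": "C55H93N15O20S2",
    "DLYLENPEIKIR": "C68H108N16O21",
    "QKR": "C17H31N7O5",
    "AVKGFR": "C31H49N9O7",
}

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.mark.parametrize("peptide,formula", sorted(DONOR_FORMULAS.items()))
def test_crosslink_modification_formulas(peptide, formula):
    """Each donor peptide's modification composition reproduces the printed formula."""
    assert xlink_modification_composition(peptide).formula() == formula


@pytest.mark.parametrize(
    "sequence,mods,expected",
    [
        ("G", None, "C2H5NO2"),
        ("QKR", None, "C17H34N8O5"),  # printed modification formula plus NH3
        ("FLKNAGR", None, "C36H60N12O9"),
        ("QM", [(1, "deamidation"), (2, "oxidation")], "C10H18N2O6S"),
    ],
)
def test_peptide_composition_examples(sequence, mods, expected):
    assert peptide_composition(sequence, mods).formula() == expected


def test_peptide_composition_rejects_bad_input():
    with pytest.raises(ChemError, match="position 2"):
        peptide_composition("AZA")
    with pytest.raises(ChemError):
        peptide_composition("")
    with pytest.raises(ChemError, match="not applicable"):
        peptide_composition("AG", [(1, "deamidation")])
    with pytest.raises(ChemError):
        peptide_composition("AG", [(5, "oxidation")])


def test_xlink_modification_requires_lysine():
    with pytest.raises(ChemError, match="lysine"):
        xlink_modification_composition("AGGR")


@settings(max_examples=50, derandomize=True)
@given(
    s1=st.text(alphabet=AA, min_size=1, max_size=12),
    s2=st.text(alphabet=AA, min_size=1, max_size=12),
)
def test_composition_concatenation_identity(s1, s2):
    """Peptide-bond formation: comp(s1+s2) = comp(s1) + comp(s2) − H2O."""
    assert peptide_composition(s1 + s2) == (
        peptide_composition(s1) + peptide_composition(s2) - WATER
    )


@settings(max_examples=50, derandomize=True)
@given(seq=st.text(alphabet=AA.replace("K", "") , min_size=1, max_size=15))
def test_mass_against_pyteomics(seq):
    """Monoisotopic masses agree with the independent pyteomics implementation."""
    seq = seq + "K"
    ours = monoisotopic_mass(peptide_composition(seq))
    theirs = ptmass.calculate_mass(sequence=seq)
    assert ours == pytest.approx(theirs, abs=1e-7)
    mod = monoisotopic_mass(xlink_modification_composition(seq))
    assert mod == pytest.approx(theirs - ptmass.calculate_mass(formula="NH3"), abs=1e-7)


def test_monoisotopic_mass_basics():
    assert monoisotopic_mass(ElementalComposition()) == 0.0
    assert monoisotopic_mass(WATER) == pytest.approx(18.0105646, abs=1e-6)
    deam = ElementalComposition({"O": 1, "H": -1, "N": -1})
    assert monoisotopic_mass(deam) == pytest.approx(0.9840156, abs=1e-6)
    assert average_mass(WATER) > monoisotopic_mass(WATER)


def test_mz_from_mass_charging():
    m = 1000.0
    assert mz_from_mass(m, 1) == pytest.approx(m + PROTON_MASS)
    assert mz_from_mass(m, 2) == pytest.approx((m + 2 * PROTON_MASS) / 2)
    with pytest.raises(ChemError):
        mz_from_mass(m, 0)


def test_formula_round_trip():
    for text in ("C36H57N11O9", "C43H62N16O11S", "H2O", "S"):
        assert ElementalComposition(text).formula() == text
    with pytest.raises(ChemError):
        ElementalComposition("C6h12")


def test_composition_arithmetic_keeps_signed_counts():
    delta = ElementalComposition("O") - ElementalComposition("NH")
    assert delta["H"] == -1 and delta["N"] == -1 and delta["O"] == 1
    assert not delta.is_physical()
    assert (delta + ElementalComposition("NH")).formula() == "O"


# --- isotope envelopes -------------------------------------------------------


def _multinomial_envelope(comp, n_peaks):
    """Exhaustive multinomial enumeration oracle (fine-grained, then binned)."""
    agg = {0: 1.0}
    for el, cnt in ElementalComposition(comp).items():
        iso = ISOTOPES[el]
        mono = min(m for m, _ in iso)
        el_dist = {}
        for combo in itertools.product(range(cnt + 1), repeat=len(iso)):
            if sum(combo) != cnt:
                continue
            coeff = math.factorial(cnt)
            prob = 1.0
            offset = 0
            for n_i, (m_i, ab_i) in zip(combo, iso):
                coeff //= math.factorial(n_i)
                prob *= ab_i ** n_i
                offset += n_i * int(round(m_i - mono))
            el_dist[offset] = el_dist.get(offset, 0.0) + coeff * prob
        agg = {
            o1 + o2: sum(
                p1 * p2
                for oo1, p1 in agg.items()
                for oo2, p2 in el_dist.items()
                if oo1 + oo2 == o1 + o2
            )
            for o1 in agg
            for o2 in el_dist
        }
    probs = np.array([agg.get(k, 0.0) for k in range(n_peaks)])
    return probs / probs.sum()


@pytest.mark.parametrize("formula", ["H2O", "C5H8N2O2", "C10S2", "C20H30N5O4"])
def test_isotope_distribution_matches_enumeration_oracle(formula):
    ours = np.array([ab for _, ab in isotope_distribution(formula, 4)])
    oracle = _multinomial_envelope(formula, 4)
    assert np.allclose(ours, oracle, atol=1e-10)


def test_isotope_distribution_small_cases():
    # single hydrogen: abundances proportional to the isotope table
    h = isotope_distribution({"H": 1}, 2)
    ab0, ab1 = (ab for _, ab in ISOTOPES["H"][:2])
    assert h[1][1] / h[0][1] == pytest.approx(ab1 / ab0, rel=1e-9)
    # C100: A+1/A ratio is 100 x the single-atom 13C/12C ratio
    c = isotope_distribution({"C": 100}, 2)
    c13 = ISOTOPES["C"][1][1] / ISOTOPES["C"][0][1]
    assert c[1][1] / c[0][1] == pytest.approx(100 * c13, rel=1e-6)


def test_isotope_distribution_contract():
    peaks = isotope_distribution("C36H57N11O9", 5)
    abundances = [ab for _, ab in peaks]
    assert sum(abundances) == pytest.approx(1.0)
    apex = int(np.argmax(abundances))
    assert all(
        abundances[i] >= abundances[i + 1] for i in range(apex, len(abundances) - 1)
    )
    masses = [m for m, _ in peaks]
    assert all(b - a == pytest.approx(1.0, abs=0.01) for a, b in zip(masses, masses[1:]))
    with pytest.raises(ChemError):
        isotope_distribution({"C": -1}, 2)
    with pytest.raises(ChemError):
        isotope_distribution("H2O", 0)
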