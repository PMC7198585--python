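"""Isopeptide model and crosslink-aware fragment calculus."""

import numpy as np
import pytest
from pyteomics import mass as ptmass

from isoxlink.chem import PROTON_MASS, monoisotopic_mass, peptide_composition
from isoxlink.isopeptide import (
    DEAMIDATION_MASS,
    FragmentConfig,
    Isopeptide,
    IsopeptideError,
    NH3_MASS,
    composition,
    count_fragment_matches,
    enumerate_fragments,
    fragment_composition,
    fragment_mz_array,
    match_fragments,
    precursor_mass,
    precursor_mz,
)


def test_isopeptide_invariants_enforced():
    with pytest.raises(IsopeptideError):
        Isopeptide("APLR", "QKR", alpha_q_pos=1, beta_k_pos=2)  # not a Q
    with pytest.raises(IsopeptideError):
        Isopeptide("AQLR", "QKR", alpha_q_pos=2, beta_k_pos=1)  # not a K
    with pytest.raises(IsopeptideError):
        Isopeptide("AQLR", "QKR", alpha_q_pos=2, beta_k_pos=2, deamidation=(2,))


def test_precursor_mass_identities(w3_isopeptide):
    iso = w3_isopeptide
    alpha_mass = monoisotopic_mass(
        peptide_composition(iso.alpha_seq, iso.side_mods("alpha"))
    )
    beta_mass = monoisotopic_mass(peptide_composition(iso.beta_seq))
    assert precursor_mass(iso) == pytest.approx(alpha_mass + beta_mass - NH3_MASS, abs=1e-9)
    # adding one deamidation shifts the precursor by the deamidation delta
    plus = Isopeptide(iso.alpha_seq, iso.beta_seq, iso.alpha_q_pos, iso.beta_k_pos,
                      deamidation=iso.deamidation + (11,))
    assert precursor_mass(plus) - precursor_mass(iso) == pytest.approx(
        DEAMIDATION_MASS, abs=1e-9
    )


def test_precursor_mass_symmetric_in_side_labels(fixture_isopeptides):
    """Relabeling which peptide is the base never changes the molecule's mass."""
    for iso in fixture_isopeptides.values():
        alpha_with_mods = monoisotopic_mass(
            peptide_composition(iso.alpha_seq, iso.side_mods("alpha"))
        )
        beta = monoisotopic_mass(peptide_composition(iso.beta_seq))
        assert precursor_mass(iso) == pytest.approx(
            beta + alpha_with_mods - NH3_MASS, abs=1e-9
        )


def test_fragments_before_crosslink_match_plain_peptide(w3_isopeptide):
    iso = w3_isopeptide
    frags = enumerate_fragments(iso, FragmentConfig(max_charge=1), sides=("alpha",))
    plain_by = {}
    for i in range(1, len(iso.alpha_seq)):
        plain_by[("b", i)] = ptmass.calculate_mass(
            sequence=iso.alpha_seq[:i], ion_type="b", charge=1
        )
        plain_by[("y", i)] = ptmass.calculate_mass(
            sequence=iso.alpha_seq[-i:], ion_type="y", charge=1
        )
    partner = monoisotopic_mass(peptide_composition(iso.beta_seq)) - NH3_MASS
    for f in frags:
        if f.ion_type not in ("b", "y") or f.loss or f.charge != 1:
            continue
        expected = plain_by[(f.ion_type, f.index)]
        covers_deam = (f.start <= 4 <= f.end)
        if covers_deam:
            expected += DEAMIDATION_MASS
        if f.carries_partner:
            expected += partner
        else:
            assert not (f.start <= iso.alpha_q_pos <= f.end)
        assert f.mz == pytest.approx(expected, abs=1e-6)


def test_plain_by_ion_count():
    iso = Isopeptide("AQLPSR", "QKR", alpha_q_pos=2, beta_k_pos=2)
    config = FragmentConfig(ion_types=("b", "y"), include_a=False, losses=(), max_charge=1)
    frags = enumerate_fragments(iso, config, sides=("alpha",))
    n = len(iso.alpha_seq)
    assert len(frags) == 2 * (n - 1)


def test_fragment_mz_recomputable_from_composition(fixture_isopeptides):
    """Stored m/z equals the mass of the fragment's elemental composition (1e-6 Da)."""
    rng = np.random.default_rng(42)
    checked = 0
    for iso in fixture_isopeptides.values():
        frags = enumerate_fragments(iso, FragmentConfig(max_charge=2))
        take = rng.choice(len(frags), size=min(40, len(frags)), replace=False)
        for i in take:
            f = frags[i]
            if f.ion_type == "internal":
                continue
            comp = fragment_composition(iso, f.side, f.ion_type, f.start, f.end, f.loss)
            expected = (monoisotopic_mass(comp) + f.charge * PROTON_MASS) / f.charge
            assert f.mz == pytest.approx(expected, abs=1e-6)
            checked += 1
    assert checked > 500


def test_by_complementarity(w3_isopeptide):
    """b_i and y_(n−i) of one side sum to that side's full species mass + 2 protons."""
    iso = w3_isopeptide
    config = FragmentConfig(ion_types=("b", "y"), include_a=False, losses=(), max_charge=1)
    frags = enumerate_fragments(iso, config, sides=("alpha",))
    b = {f.index: f.mz for f in frags if f.ion_type == "b"}
    y = {f.index: f.mz for f in frags if f.ion_type == "y"}
    total = precursor_mass(iso)
    n = len(iso.alpha_seq)
    for i in range(1, n):
        assert b[i] + y[n - i] == pytest.approx(total + 2 * PROTON_MASS, abs=1e-6)


def test_reciprocal_enumeration_spanning_set(fixture_isopeptides):
    """Swapping which side is enumerated first leaves the fragment m/z set unchanged."""
    for iso in list(fixture_isopeptides.values())[:5]:
        fwd = enumerate_fragments(iso, sides=("alpha", "beta"))
        rev = enumerate_fragments(iso, sides=("beta", "alpha"))
        key = lambda f: (f.side, f.ion_type, f.start, f.end, f.loss, f.charge)
        assert {key(f): f.mz for f in fwd} == {key(f): f.mz for f in rev}


def test_internal_fragments_are_interior_and_bounded(w3_isopeptide):
    config = FragmentConfig(internal=True, internal_length=(2, 6), max_charge=1)
    frags = enumerate_fragments(w3_isopeptide, config, sides=("alpha",))
    inner = [f for f in frags if f.ion_type == "internal"]
    n = len(w3_isopeptide.alpha_seq)
    assert inner
    for f in inner:
        assert 2 <= f.start and f.end <= n - 1
        assert 2 <= f.end - f.start + 1 <= 6


def test_spanning_truncation_adds_partner_subfragments(w3_isopeptide):
    base = enumerate_fragments(w3_isopeptide, FragmentConfig(max_charge=1))
    more = enumerate_fragments(
        w3_isopeptide, FragmentConfig(max_charge=1, spanning_truncation=True)
    )
    extra = [f for f in more if f.ion_type == "internal"]
    assert len(more) > len(base)
    assert all(f.carries_partner for f in extra)


def test_unsupported_ion_type_rejected():
    with pytest.raises(IsopeptideError):
        FragmentConfig(ion_types=("b", "c"))


def test_fast_mz_path_equals_enumeration(fixture_isopeptides):
    for iso in list(fixture_isopeptides.values())[:8]:
        for config in (FragmentConfig(), FragmentConfig(max_charge=3, loss_mode="always")):
            slow = np.sort([f.mz for f in enumerate_fragments(iso, config)])
            fast = fragment_mz_array(iso, config)
            assert np.allclose(slow, fast, atol=1e-9)


def test_match_fragments_rules(w3_isopeptide):
    frags = enumerate_fragments(w3_isopeptide, FragmentConfig(max_charge=1))
    mzs = np.sort(np.array([f.mz for f in frags]))
    ints = np.ones_like(mzs)
    matches = match_fragments(mzs, ints, frags, tol=0.5)
    assert len(matches) == len(frags)  # exact spectrum: everything matched

    one = frags[:1]
    off = np.array([one[0].mz + 0.6])
    assert match_fragments(off, np.ones(1), one, tol=0.5) == []

    # two peaks within tolerance: nearer wins; exact ties go to higher intensity
    target = one[0].mz
    peaks = np.array([target - 0.3, target + 0.1, target + 0.4])
    intensities = np.array([10.0, 1.0, 99.0])
    [(f, j)] = match_fragments(peaks, intensities, one, tol=0.5)
    assert j == 1
    tie_peaks = np.array([target - 0.2, target + 0.2])
    [(f, j)] = match_fragments(tie_peaks, np.array([1.0, 5.0]), one, tol=0.5)
    assert j == 1
    assert count_fragment_matches(np.array([target]), peaks, intensities, 0.5) == 1


def test_match_is_one_to_one(w3_isopeptide):
    frags = enumerate_fragments(w3_isopeptide, FragmentConfig(max_charge=2))
    mzs = np.sort(np.array([f.mz for f in frags]))
    matches = match_fragments(mzs, np.ones_like(mzs), frags, tol=0.5)
    peak_ids = [j for _, j in matches]
    assert len(peak_ids) == len(set(peak_ids))


def test_precursor_mz_charge_range(w3_isopeptide):
    m = precursor_mass(w3_isopeptide)
    assert precursor_mz(w3_isopeptide, 3) == pytest.approx((m + 3 * PROTON_MASS) / 3)
    with pytest.raises(IsopeptideError):
        precursor_mz(w3_isopeptide, 6)
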