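"""Elemental-composition arithmetic for peptides and isopeptide crosslink modifications.

The N^ε^-(γ-glutamyl)-lysine isopeptide bond between a glutamine side chain and a
lysine ε-amine forms with loss of one ammonia.  A crosslinked partner peptide can
therefore be treated as a variable modification whose elemental composition is the
intact peptide composition minus NH3; everything downstream (precursor masses,
fragment m/z, isotope envelopes) reduces to composition arithmetic, which this
module provides.

Compositions are signed element→count maps: physical molecules have non-negative
counts, while modification deltas (deamidation = −H −N +O) may be negative.
Monoisotopic masses are used throughout; average masses are available but never
used in matching.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyteomics import mass as _ptmass

__all__ = [
    "ElementalComposition",
    "RESIDUE_COMPOSITIONS",
    "WATER",
    "AMMONIA",
    "PROTON_MASS",
    "DEAMIDATION_DELTA",
    "OXIDATION_DELTA",
    "MODIFICATION_DELTAS",
    "peptide_composition",
    "xlink_modification_composition",
    "monoisotopic_mass",
    "average_mass",
    "mz_from_mass",
    "isotope_distribution",
]


class ChemError(ValueError):
    """Raised for invalid residues, formulas or compositions."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class ElementalComposition(Counter):
    """Signed integer element counts with element-wise +/- and formula round-trip.

    The text dialect is Hill-like ("C36H57N11O9") with implicit count 1 for a
    bare symbol (e.g. the trailing S in "C43H62N16O11S").
    """

    def __init__(self, arg=None, **kwargs):
        if isinstance(arg, str):
            super().__init__()
            self._parse(arg)
            self.update(kwargs)
        elif arg is None:
            super().__init__(**kwargs)
        else:
            super().__init__(arg, **kwargs)
        self._drop_zeros()

    def _parse(self, formula: str) -> None:
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ChemError(f"cannot parse formula {formula!r} at offset {pos}")
            element, count = match.group(1), match.group(2)
            self[element] += int(count) if count else 1
            pos = match.end()
        if pos != len(formula):
            raise ChemError(f"cannot parse formula {formula!r} at offset {pos}")

    def _drop_zeros(self) -> None:
        for element in [el for el, n in self.items() if n == 0]:
            del self[element]

    # Counter.__add__/__sub__ drop non-positive counts; compositions must keep
    # signed counts so deltas like deamidation (−H −N +O) survive arithmetic.
    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = ElementalComposition(self)
        for el, n in other.items():
            out[el] += n
        out._drop_zeros()
        return out

    def __sub__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = ElementalComposition(self)
        for el, n in other.items():
            out[el] -= n
        out._drop_zeros()
        return out

    def __mul__(self, k: int) -> "ElementalComposition":
        out = ElementalComposition({el: n * k for el, n in self.items()})
        out._drop_zeros()
        return out

    __rmul__ = __mul__

    def is_physical(self) -> bool:
        """True when every count is non-negative (a real molecule, not a delta)."""
        return all(n >= 0 for n in self.values())

    def formula(self) -> str:
        """Hill-ordered formula string; inverse of the constructor."""
        parts = []
        ordered = [el for el in ("C", "H") if el in self]
        ordered += sorted(el for el in self if el not in ("C", "H"))
        for el in ordered:
            n = self[el]
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementalComposition({self.formula()!r})"


# --- constants ---------------------------------------------------------------

#: Monoisotopic atomic masses (most abundant isotope), NIST values via pyteomics.
ATOMIC_MASS: dict[str, float] = {}
#: Per element: list of (exact isotope mass, relative abundance), abundance-summing to 1.
ISOTOPES: dict[str, list[tuple[float, float]]] = {}

for _el in ("C", "H", "N", "O", "S", "P", "Se"):
    _table = _ptmass.nist_mass[_el]
    _iso = sorted(
        (m, ab) for key, (m, ab) in _table.items() if key != 0 and ab > 0
    )
    ISOTOPES[_el] = _iso
    ATOMIC_MASS[_el] = max(_iso, key=lambda t: t[1])[0]

#: Mass of a proton, used for charging: m/z = (M + z * proton) / z.
PROTON_MASS = 1.007276466

# Residue (amino-acid minus water) compositions of the 20 standard residues.
# Cysteine is the free thiol: no alkylation is applied by default, which is what
# reproduces the printed WKNHGCQR crosslink-modification formula.
RESIDUE_COMPOSITIONS: dict[str, ElementalComposition] = {
    "G": ElementalComposition("C2H3NO"),
    "A": ElementalComposition("C3H5NO"),
    "S": ElementalComposition("C3H5NO2"),
    "P": ElementalComposition("C5H7NO"),
    "V": ElementalComposition("C5H9NO"),
    "T": ElementalComposition("C4H7NO2"),
    "C": ElementalComposition("C3H5NOS"),
    "L": ElementalComposition("C6H11NO"),
    "I": ElementalComposition("C6H11NO"),
    "N": ElementalComposition("C4H6N2O2"),
    "D": ElementalComposition("C4H5NO3"),
    "Q": ElementalComposition("C5H8N2O2"),
    "K": ElementalComposition("C6H12N2O"),
    "E": ElementalComposition("C5H7NO3"),
    "M": ElementalComposition("C5H9NOS"),
    "H": ElementalComposition("C6H7N3O"),
    "F": ElementalComposition("C9H9NO"),
    "R": ElementalComposition("C6H12N4O"),
    "Y": ElementalComposition("C9H9NO2"),
    "W": ElementalComposition("C11H10N2O"),
}

WATER = ElementalComposition("H2O")
AMMONIA = ElementalComposition("NH3")
CARBON_MONOXIDE = ElementalComposition("CO")

#: Deamidation Q/N → E/D: −H −N +O, +0.98402 Da.
DEAMIDATION_DELTA = ElementalComposition({"H": -1, "N": -1, "O": 1})
#: Methionine oxidation: +O.
OXIDATION_DELTA = ElementalComposition("O")
#: Cysteine carbamidomethylation; available but off by default (free thiol).
CARBAMIDOMETHYL_DELTA = ElementalComposition("C2H3NO")

MODIFICATION_DELTAS: dict[str, ElementalComposition] = {
    "deamidation": DEAMIDATION_DELTA,
    "oxidation": OXIDATION_DELTA,
    "carbamidomethyl": CARBAMIDOMETHYL_DELTA,
}

#: Residues a named modification may sit on.
MODIFICATION_TARGETS: dict[str, frozenset[str]] = {
    "deamidation": frozenset("NQ"),
    "oxidation": frozenset("M"),
    "carbamidomethyl": frozenset("C"),
}


# --- operations --------------------------------------------------------------


def residue_composition(residue: str, position: int | None = None) -> ElementalComposition:
    try:
        return RESIDUE_COMPOSITIONS[residue]
    except KeyError:
        where = f" at position {position}" if position is not None else ""
        raise ChemError(f"unknown residue symbol {residue!r}{where}") from None


def peptide_composition(
    sequence: str,
    mods: Sequence[tuple[int, str]] | None = None,
) -> ElementalComposition:
    """Elemental composition of a linear peptide with positioned modifications.

    Parameters
    ----------
    sequence
        Residue string (standard one-letter codes).
    mods
        ``(position, name)`` pairs with 1-based positions;
        names are keys of :data:`MODIFICATION_DELTAS`.
    """
    if not sequence:
        raise ChemError("empty peptide sequence")
    comp = ElementalComposition(WATER)
    for i, res in enumerate(sequence, start=1):
        comp = comp + residue_composition(res, i)
    for pos, name in mods or ():
        if not 1 <= pos <= len(sequence):
            raise ChemError(f"modification position {pos} outside 1..{len(sequence)}")
        if name not in MODIFICATION_DELTAS:
            raise ChemError(f"unknown modification {name!r}")
        if sequence[pos - 1] not in MODIFICATION_TARGETS[name]:
            raise ChemError(
                f"{name} not applicable to residue {sequence[pos - 1]!r} at position {pos}"
            )
        comp = comp + MODIFICATION_DELTAS[name]
    return comp


def xlink_modification_composition(beta_sequence: str) -> ElementalComposition:
    """Composition of a lysine-containing peptide used as a crosslink modification.

    The isopeptide (transamidation) bond forms with release of one ammonia, so
    the partner peptide contributes its full composition minus NH3.
    """
    comp = peptide_composition(beta_sequence)
    if "K" not in beta_sequence:
        raise ChemError(
            f"peptide {beta_sequence!r} has no lysine; cannot form an isopeptide bond"
        )
    out = comp - AMMONIA
    assert out.is_physical()
    return out


def monoisotopic_mass(comp: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da: sum of count x most-abundant-isotope mass."""
    total = 0.0
    for el, n in comp.items():
        try:
            total += n * ATOMIC_MASS[el]
        except KeyError:
            raise ChemError(f"no monoisotopic mass for element {el!r}") from None
    return total


def average_mass(comp: Mapping[str, int]) -> float:
    """Abundance-weighted average mass in Da (informational; never used in matching)."""
    total = 0.0
    for el, n in comp.items():
        try:
            iso = ISOTOPES[el]
        except KeyError:
            raise ChemError(f"no isotope table for element {el!r}") from None
        total += n * sum(m * ab for m, ab in iso)
    return total


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a protonated species: (M + z * proton) / z."""
    if charge < 1:
        raise ChemError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def peptide_mass(sequence: str, mods: Sequence[tuple[int, str]] | None = None) -> float:
    return monoisotopic_mass(peptide_composition(sequence, mods))


# --- isotope distributions ---------------------------------------------------


def _atom_offset_distribution(element: str, max_offset: int) -> tuple[np.ndarray, np.ndarray]:
    """(probability, probability-weighted mass) arrays indexed by nominal offset."""
    iso = ISOTOPES[element]
    mono = min(m for m, _ in iso)  # lightest isotope defines offset 0 for C,H,N,O,S
    prob = np.zeros(max_offset + 1)
    wmass = np.zeros(max_offset + 1)
    for m, ab in iso:
        k = int(round(m - mono))
        if k <= max_offset:
            prob[k] += ab
            wmass[k] += ab * m
    return prob, wmass


def _convolve_tracked(pa, sa, pb, sb, max_offset):
    """Convolve two (prob, prob*mass) pairs, truncating at max_offset."""
    n = max_offset + 1
    prob = np.convolve(pa, pb)[:n]
    # expected-mass bookkeeping: S_k = sum_{i+j=k} (Sa_i Pb_j + Pa_i Sb_j)
    smass = (np.convolve(sa, pb) + np.convolve(pa, sb))[:n]
    return prob, smass


def isotope_distribution(
    comp: Mapping[str, int], n_peaks: int = 4
) -> list[tuple[float, float]]:
    """Aggregated isotopologue envelope of a physical composition.

    Peaks are binned by nominal mass offset (A, A+1, ...), computed by exact
    per-element binomial/multinomial convolution; the returned ``n_peaks``
    abundances are renormalized to sum to 1.  Each peak's mass is the
    abundance-weighted mean of the exact isotopologue masses in its bin.

    Returns a list of ``(mass, relative_abundance)`` pairs.
    """
    if n_peaks < 1:
        raise ChemError("n_peaks must be >= 1")
    comp = ElementalComposition(comp)
    if not comp.is_physical():
        raise ChemError(f"negative counts in composition {comp.formula()!r}")
    max_offset = n_peaks + 3  # guard bins so truncation does not skew the head
    prob = np.zeros(max_offset + 1)
    smass = np.zeros(max_offset + 1)
    prob[0] = 1.0
    for element, count in comp.items():
        if count == 0:
            continue
        if element not in ISOTOPES:
            raise ChemError(f"no isotope table for element {element!r}")
        pa, sa = _atom_offset_distribution(element, max_offset)
        # binary exponentiation of the per-atom distribution
        k = count
        while k:
            if k & 1:
                prob, smass = _convolve_tracked(prob, smass, pa, sa, max_offset)
            k >>= 1
            if k:
                pa, sa = _convolve_tracked(pa, sa, pa, sa, max_offset)
    head_p = prob[:n_peaks]
    head_s = smass[:n_peaks]
    total = head_p.sum()
    if total <= 0:
        raise ChemError("degenerate isotope distribution")
    peaks = []
    for p, s in zip(head_p, head_s):
        mean_mass = s / p if p > 0 else 0.0
        peaks.append((mean_mass, p / total))
    return peaks


def isotope_abundances(comp: Mapping[str, int], n_peaks: int = 4) -> np.ndarray:
    """Convenience: just the normalized abundance vector of the envelope."""
    return np.array([ab for _, ab in isotope_distribution(comp, n_peaks)])
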