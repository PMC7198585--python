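"""Crosslinked-species data model and theoretical fragment-ion enumeration.

An isopeptide is a gluten peptide (α-side) joined through a glutamine side
chain to the ε-amine of a lysine in a transglutaminase peptide (β-side); the
bond forms with loss of NH3.  For fragment calculus either side can serve as
the *base* sequence whose b/y/a/internal ladders are enumerated, with the
partner peptide treated as a mass tag attached at the crosslink residue: any
fragment that covers the crosslink position carries the full partner
composition minus NH3.  Enumerating from both bases ("reciprocal"
representations) yields the same spanning-ion m/z set, which is what makes
reversed searches and reversed targeted methods consistent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chem import (
    AMMONIA,
    CARBON_MONOXIDE,
    DEAMIDATION_DELTA,
    ElementalComposition,
    PROTON_MASS,
    RESIDUE_COMPOSITIONS,
    WATER,
    ChemError,
    monoisotopic_mass,
    mz_from_mass,
    peptide_composition,
    residue_composition,
    xlink_modification_composition,
)
from .digestion import Peptide

__all__ = [
    "Isopeptide",
    "TheoreticalFragment",
    "FragmentConfig",
    "enumerate_fragments",
    "match_fragments",
    "precursor_mass",
    "precursor_mz",
]

#: Upper bounds from the acquisition/annotation conventions used throughout.
MAX_PRECURSOR_CHARGE = 5
MAX_FRAGMENT_CHARGE = 3

#: Residues that gate water / ammonia neutral losses in "residue-gated" mode.
WATER_LOSS_RESIDUES = frozenset("STED")
AMMONIA_LOSS_RESIDUES = frozenset("RKNQ")

NH3_MASS = monoisotopic_mass(AMMONIA)
WATER_MASS = monoisotopic_mass(WATER)
CO_MASS = monoisotopic_mass(CARBON_MONOXIDE)
DEAMIDATION_MASS = monoisotopic_mass(DEAMIDATION_DELTA)


def _as_sequence(p: "Peptide | str") -> str:
    return p.sequence if isinstance(p, Peptide) else p


class IsopeptideError(ValueError):
    pass


@dataclass(frozen=True)
class Isopeptide:
    """A gluten peptide (α) crosslinked Q↔K to a TG2 peptide (β).

    ``alpha_q_pos`` / ``beta_k_pos`` are 1-based positions of the bonded
    glutamine / lysine.  ``deamidation`` lists further deamidated α-side
    positions (never the crosslinked Q itself); ``oxidation`` lists oxidised
    methionines per side.
    """

    alpha: "Peptide | str"
    beta: "Peptide | str"
    alpha_q_pos: int
    beta_k_pos: int
    deamidation: tuple[int, ...] = ()
    oxidation_alpha: tuple[int, ...] = ()
    oxidation_beta: tuple[int, ...] = ()
    identifier: str = ""

    def __post_init__(self):
        a, b = self.alpha_seq, self.beta_seq
        if not (1 <= self.alpha_q_pos <= len(a)) or a[self.alpha_q_pos - 1] != "Q":
            raise IsopeptideError(
                f"alpha position {self.alpha_q_pos} of {a!r} is not a glutamine"
            )
        if not (1 <= self.beta_k_pos <= len(b)) or b[self.beta_k_pos - 1] != "K":
            raise IsopeptideError(
                f"beta position {self.beta_k_pos} of {b!r} is not a lysine"
            )
        for pos in self.deamidation:
            if pos == self.alpha_q_pos:
                raise IsopeptideError("deamidation cannot sit on the crosslinked Q")
            if not (1 <= pos <= len(a)) or a[pos - 1] not in "NQ":
                raise IsopeptideError(f"deamidation position {pos} of {a!r} is not N/Q")
        object.__setattr__(self, "deamidation", tuple(sorted(self.deamidation)))

    @property
    def alpha_seq(self) -> str:
        return _as_sequence(self.alpha)

    @property
    def beta_seq(self) -> str:
        return _as_sequence(self.beta)

    def n_modifications(self) -> int:
        """Variable modifications on the searched (α) peptide: crosslink + deamidations + oxidations."""
        return 1 + len(self.deamidation) + len(self.oxidation_alpha)

    def side_mods(self, side: str) -> list[tuple[int, str]]:
        if side == "alpha":
            return [(p, "deamidation") for p in self.deamidation] + [
                (p, "oxidation") for p in self.oxidation_alpha
            ]
        return [(p, "oxidation") for p in self.oxidation_beta]

def composition(iso: Isopeptide) -> ElementalComposition:
    """Neutral elemental composition of the whole crosslinked species."""
    return (
        peptide_composition(iso.alpha_seq, iso.side_mods("alpha"))
        + peptide_composition(iso.beta_seq, iso.side_mods("beta"))
        - AMMONIA
    )


def precursor_mass(iso: Isopeptide) -> float:
    """Neutral monoisotopic mass; symmetric in which side is called α or β."""
    return monoisotopic_mass(composition(iso))


def precursor_mz(iso: Isopeptide, charge: int) -> float:
    if not 1 <= charge <= MAX_PRECURSOR_CHARGE:
        raise IsopeptideError(f"precursor charge {charge} outside 1..{MAX_PRECURSOR_CHARGE}")
    return mz_from_mass(precursor_mass(iso), charge)


@dataclass(frozen=True)
class FragmentConfig:
    """Which ion series, losses and charges to enumerate.

    ``loss_mode`` is ``"residue-gated"`` (H2O only from S/T/E/D-containing
    fragments, NH3 only from R/K/N/Q-containing ones) or ``"always"``.
    Internal ions are interior b-type pieces of the base sequence;
    ``spanning_truncation`` additionally truncates the attached partner to a
    b/y sub-fragment that still contains its crosslink residue.
    """

    ion_types: tuple[str, ...] = ("b", "y")
    include_a: bool = True
    losses: tuple[str, ...] = ("H2O", "NH3")
    loss_mode: str = "residue-gated"
    max_charge: int = 2
    internal: bool = False
    internal_length: tuple[int, int] = (2, 12)
    spanning_truncation: bool = False

    def __post_init__(self):
        bad = set(self.ion_types) - {"a", "b", "y"}
        if bad:
            raise IsopeptideError(f"unsupported ion type(s): {sorted(bad)}")
        if not 1 <= self.max_charge <= MAX_FRAGMENT_CHARGE:
            raise IsopeptideError(
                f"fragment charge must be 1..{MAX_FRAGMENT_CHARGE}, got {self.max_charge}"
            )


@dataclass(frozen=True)
class TheoreticalFragment:
    """One enumerated ion of one side of an isopeptide.

    ``start``/``end`` are 1-based inclusive bounds on the base side;
    ``index`` is the ladder index (i of b_i / y_i; 0 for internal ions);
    ``carries_partner`` marks fragments containing the crosslink site and thus
    the partner-peptide mass minus NH3.
    """

    side: str  # "alpha" | "beta"
    ion_type: str  # "a" | "b" | "y" | "internal"
    start: int
    end: int
    index: int
    loss: str  # "" | "H2O" | "NH3"
    charge: int
    mz: float
    carries_partner: bool

    @property
    def label(self) -> str:
        core = (
            f"{self.ion_type}{self.index}" if self.ion_type != "internal"
            else f"int[{self.start}-{self.end}]"
        )
        tag = {"alpha": "α", "beta": "β"}[self.side]
        loss = f"-{self.loss}" if self.loss else ""
        return f"{core}{tag}{loss}^{self.charge}+"


def _segment_composition(seq: str, mods: Sequence[tuple[int, str]], start: int, end: int):
    """Sum of residue compositions over [start, end] with in-range modifications (no water)."""
    comp = ElementalComposition()
    for i in range(start, end + 1):
        comp = comp + residue_composition(seq[i - 1], i)
    for pos, name in mods:
        if start <= pos <= end:
            from .chem import MODIFICATION_DELTAS

            comp = comp + MODIFICATION_DELTAS[name]
    return comp


def fragment_composition(
    iso: Isopeptide,
    side: str,
    ion_type: str,
    start: int,
    end: int,
    loss: str = "",
) -> ElementalComposition:
    """Neutral composition of a fragment; the oracle behind every stored m/z."""
    if side == "alpha":
        seq, mods, xpos = iso.alpha_seq, iso.side_mods("alpha"), iso.alpha_q_pos
        partner = xlink_modification_composition(iso.beta_seq) + _mods_delta(
            iso.side_mods("beta")
        )
    else:
        seq, mods, xpos = iso.beta_seq, iso.side_mods("beta"), iso.beta_k_pos
        partner = (
            peptide_composition(iso.alpha_seq, iso.side_mods("alpha")) - AMMONIA
        )
    comp = _segment_composition(seq, mods, start, end)
    if ion_type in ("y",):
        comp = comp + WATER
    if ion_type == "a":
        comp = comp - CARBON_MONOXIDE
    if start <= xpos <= end:
        comp = comp + partner
    if loss == "H2O":
        comp = comp - WATER
    elif loss == "NH3":
        comp = comp - AMMONIA
    elif loss:
        raise IsopeptideError(f"unknown loss {loss!r}")
    return comp


def _mods_delta(mods: Sequence[tuple[int, str]]) -> ElementalComposition:
    from .chem import MODIFICATION_DELTAS

    comp = ElementalComposition()
    for _, name in mods:
        comp = comp + MODIFICATION_DELTAS[name]
    return comp


def _loss_variants(seq_piece: str, carries_partner: bool, config: FragmentConfig):
    yield ""
    for loss in config.losses:
        if config.loss_mode == "always":
            yield loss
        elif loss == "H2O" and (set(seq_piece) & WATER_LOSS_RESIDUES):
            yield loss
        elif loss == "NH3" and (
            (set(seq_piece) & AMMONIA_LOSS_RESIDUES) or carries_partner
        ):
            yield loss


def _side_params(iso: Isopeptide, side: str):
    if side == "alpha":
        return iso.alpha_seq, iso.alpha_q_pos
    return iso.beta_seq, iso.beta_k_pos


def enumerate_fragments(
    iso: Isopeptide,
    config: FragmentConfig | None = None,
    sides: Sequence[str] = ("alpha", "beta"),
) -> list[TheoreticalFragment]:
    """All theoretical fragments of both sides of an isopeptide.

    For each requested side, prefix (b, and a = b − CO) and suffix (y) ions of
    every length are enumerated; ions covering the crosslink position carry the
    partner mass.  Internal ions are contiguous interior pieces (b-type).
    Neutral-loss variants and charges 1..``max_charge`` are applied; the result
    has no duplicate (side, type, bounds, loss, charge) entries.
    """
    config = config or FragmentConfig()
    out: dict[tuple, TheoreticalFragment] = {}

    def add(side, ion_type, start, end, index, carries, seq_piece):
        base = fragment_composition(iso, side, ion_type, start, end)
        base_mass = monoisotopic_mass(base)
        for loss in _loss_variants(seq_piece, carries, config):
            if ion_type == "a" and loss:
                continue  # CO loss only, realized as the a-ion itself
            mass = base_mass
            if loss == "H2O":
                mass -= WATER_MASS
            elif loss == "NH3":
                mass -= NH3_MASS
            for z in range(1, config.max_charge + 1):
                key = (side, ion_type, start, end, loss, z)
                if key not in out:
                    out[key] = TheoreticalFragment(
                        side, ion_type, start, end, index, loss, z,
                        mz_from_mass(mass, z), carries,
                    )

    want_b = "b" in config.ion_types
    want_y = "y" in config.ion_types
    want_a = config.include_a or "a" in config.ion_types

    for side in sides:
        seq, xpos = _side_params(iso, side)
        n = len(seq)
        for i in range(1, n):  # prefixes b_i / a_i, i = 1..n-1
            piece = seq[:i]
            carries = xpos <= i
            if want_b:
                add(side, "b", 1, i, i, carries, piece)
            if want_a:
                add(side, "a", 1, i, i, carries, piece)
        for i in range(1, n):  # suffixes y_i, i = 1..n-1
            start = n - i + 1
            piece = seq[start - 1:]
            carries = xpos >= start
            if want_y:
                add(side, "y", start, n, i, carries, piece)
        if config.internal:
            lo, hi = config.internal_length
            for start in range(2, n):  # exclude both termini
                for end in range(start + lo - 1, min(n - 1, start + hi - 1) + 1):
                    piece = seq[start - 1:end]
                    carries = start <= xpos <= end
                    add(side, "internal", start, end, 0, carries, piece)
        if config.spanning_truncation:
            _add_spanning_truncations(iso, side, config, out)

    return sorted(out.values(), key=lambda f: (f.mz, f.side, f.ion_type, f.start, f.end, f.loss, f.charge))


def _add_spanning_truncations(iso, side, config, out):
    """Spanning ions whose attached partner is itself a b/y sub-fragment.

    The partner piece must contain its own crosslink residue; the combined
    neutral composition is base piece + partner piece − NH3.
    """
    seq, xpos = _side_params(iso, side)
    pseq, pxpos = _side_params(iso, "beta" if side == "alpha" else "alpha")
    pmods = iso.side_mods("beta" if side == "alpha" else "alpha")
    n, pn = len(seq), len(pseq)
    mods = iso.side_mods(side)
    partner_pieces = []
    for j in range(1, pn):  # proper sub-fragments only
        if pxpos <= j:  # b_j piece covers partner crosslink residue
            partner_pieces.append(("b", 1, j, _segment_composition(pseq, pmods, 1, j)))
        if pxpos >= pn - j + 1:  # y_j piece
            partner_pieces.append(
                ("y", pn - j + 1, pn, _segment_composition(pseq, pmods, pn - j + 1, pn) + WATER)
            )
    for i in range(1, n):
        for base_type, start, end in (("b", 1, i), ("y", n - i + 1, n)):
            if base_type not in config.ion_types:
                continue
            if not (start <= xpos <= end):
                continue
            base = _segment_composition(seq, mods, start, end)
            if base_type == "y":
                base = base + WATER
            for ptype, pstart, pend, pcomp in partner_pieces:
                mass = monoisotopic_mass(base + pcomp - AMMONIA)
                for z in range(1, config.max_charge + 1):
                    key = (side, f"{base_type}*{ptype}{pend - pstart + 1}", start, end, "", z)
                    if key not in out:
                        out[key] = TheoreticalFragment(
                            side, "internal", start, end, 0, "", z,
                            mz_from_mass(mass, z), True,
                        )


_RESIDUE_MASS = {r: monoisotopic_mass(c) for r, c in RESIDUE_COMPOSITIONS.items()}
_MOD_MASS = {"deamidation": DEAMIDATION_MASS, "oxidation": monoisotopic_mass(
    ElementalComposition("O")), "carbamidomethyl": monoisotopic_mass(ElementalComposition("C2H3NO"))}


def fragment_mz_array(
    iso: Isopeptide,
    config: FragmentConfig | None = None,
    sides: Sequence[str] = ("alpha", "beta"),
) -> np.ndarray:
    """Sorted m/z values of the same fragment set as :func:`enumerate_fragments`.

    A numeric fast path (cumulative residue masses, no composition objects)
    used for scoring large placement enumerations; falls back to the full
    enumeration when internal or partner-truncated ions are requested.
    """
    config = config or FragmentConfig()
    if config.internal or config.spanning_truncation:
        return np.array([f.mz for f in enumerate_fragments(iso, config, sides)])
    want_b = "b" in config.ion_types
    want_y = "y" in config.ion_types
    want_a = config.include_a or "a" in config.ion_types
    losses = config.losses
    always = config.loss_mode == "always"
    mzs: list[float] = []
    for side in sides:
        seq, xpos = _side_params(iso, side)
        mods = iso.side_mods(side)
        if side == "alpha":
            partner = monoisotopic_mass(xlink_modification_composition(iso.beta_seq)) + sum(
                _MOD_MASS[name] for _, name in iso.side_mods("beta")
            )
        else:
            partner = (
                monoisotopic_mass(peptide_composition(iso.alpha_seq, iso.side_mods("alpha")))
                - NH3_MASS
            )
        n = len(seq)
        res = np.array([_RESIDUE_MASS[r] for r in seq])
        for pos, name in mods:
            res[pos - 1] += _MOD_MASS[name]
        pre = np.cumsum(res)
        total = float(pre[-1])
        # cumulative loss-eligibility flags
        w_pre = np.maximum.accumulate(np.array([r in WATER_LOSS_RESIDUES for r in seq]))
        n_pre = np.maximum.accumulate(np.array([r in AMMONIA_LOSS_RESIDUES for r in seq]))
        w_suf = np.maximum.accumulate(np.array([r in WATER_LOSS_RESIDUES for r in seq])[::-1])[::-1]
        n_suf = np.maximum.accumulate(np.array([r in AMMONIA_LOSS_RESIDUES for r in seq])[::-1])[::-1]

        def push(neutral, water_ok, ammonia_ok, is_a=False):
            variants = [neutral]
            if not is_a:
                for loss in losses:
                    if loss == "H2O" and (always or water_ok):
                        variants.append(neutral - WATER_MASS)
                    elif loss == "NH3" and (always or ammonia_ok):
                        variants.append(neutral - NH3_MASS)
            for m in variants:
                for z in range(1, config.max_charge + 1):
                    mzs.append((m + z * PROTON_MASS) / z)

        for i in range(1, n):
            carries = xpos <= i
            b = float(pre[i - 1]) + (partner if carries else 0.0)
            if want_b:
                push(b, w_pre[i - 1], n_pre[i - 1] or carries)
            if want_a:
                push(b - CO_MASS, False, False, is_a=True)
        for i in range(1, n):
            start = n - i + 1
            carries = xpos >= start
            y = total - float(pre[start - 2]) + WATER_MASS + (partner if carries else 0.0)
            if want_y:
                push(y, w_suf[start - 1], n_suf[start - 1] or carries)
    return np.sort(np.array(mzs))


def count_fragment_matches(
    theoretical_mz: np.ndarray,
    peaks_mz: np.ndarray,
    peaks_intensity: np.ndarray,
    tol: float,
) -> int:
    """One-to-one greedy match count; same assignment rule as :func:`match_fragments`."""
    taken: set[int] = set()
    count = 0
    for mz in theoretical_mz:  # already sorted
        lo = np.searchsorted(peaks_mz, mz - tol, side="left")
        hi = np.searchsorted(peaks_mz, mz + tol, side="right")
        best = None
        for j in range(lo, hi):
            if j in taken:
                continue
            cand = (abs(peaks_mz[j] - mz), -peaks_intensity[j], j)
            if best is None or cand < best:
                best = cand
        if best is not None:
            taken.add(best[2])
            count += 1
    return count


def match_fragments(
    peaks_mz: np.ndarray,
    peaks_intensity: np.ndarray,
    fragments: Sequence[TheoreticalFragment],
    tol: float = 0.5,
) -> list[tuple[TheoreticalFragment, int]]:
    """Greedy one-to-one assignment of theoretical fragments to observed peaks.

    Peaks must be sorted by m/z.  Each fragment takes the nearest unclaimed
    peak within ``tol`` Da; ties on distance are broken toward the more intense
    peak, then the lower index.  Fragments are processed in the deterministic
    enumeration order, so the result is reproducible.
    """
    if tol <= 0:
        raise IsopeptideError("tolerance must be positive")
    peaks_mz = np.asarray(peaks_mz, dtype=float)
    peaks_intensity = np.asarray(peaks_intensity, dtype=float)
    taken: set[int] = set()
    matches: list[tuple[TheoreticalFragment, int]] = []
    order = sorted(
        range(len(fragments)),
        key=lambda k: (
            fragments[k].mz, fragments[k].side, fragments[k].ion_type,
            fragments[k].start, fragments[k].end, fragments[k].loss, fragments[k].charge,
        ),
    )
    for k in order:
        frag = fragments[k]
        lo = np.searchsorted(peaks_mz, frag.mz - tol, side="left")
        hi = np.searchsorted(peaks_mz, frag.mz + tol, side="right")
        best = None
        for j in range(lo, hi):
            if j in taken:
                continue
            cand = (abs(peaks_mz[j] - frag.mz), -peaks_intensity[j], j)
            if best is None or cand < best:
                best = cand
        if best is not None:
            taken.add(best[2])
            matches.append((frag, best[2]))
    return matches
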