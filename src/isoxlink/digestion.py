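"""In-silico proteolysis of gluten proteins and of transglutaminase 2 (TG2).

Gluten protein types are hydrolysed with a gastrointestinal enzyme cocktail
(pepsin, then trypsin + chymotrypsin); the TG2 carrier protein is digested with
trypsin alone, and the crosslink-donor peptides of interest are the tryptic
peptides that contain exactly one lysine.  Cleavage rules are the conventional
site definitions:

* trypsin — after K/R, not before P
* chymotrypsin (high specificity) — after F/Y/W, not before P
* pepsin (pH 1.3–2 convention) — after F/L, not before P

Combined digests cleave at the union of the active enzymes' sites, and missed
cleavages are counted against that union.  Coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CleavageRule",
    "Peptide",
    "TRYPSIN",
    "CHYMOTRYPSIN",
    "PEPSIN",
    "ENZYMES",
    "GASTROINTESTINAL",
    "cleavage_sites",
    "digest",
    "tg2_donor_peptides",
    "STUDY_DONOR_PEPTIDES",
    "DONOR_LYSINES",
]


class DigestionError(ValueError):
    pass


@dataclass(frozen=True)
class CleavageRule:
    """Cleave C-terminal to any residue in ``p1`` unless followed by one in ``p1_exclusion``."""

    name: str
    p1: frozenset[str]
    p1_exclusion: frozenset[str] = frozenset()

    def cuts_after(self, sequence: str, i: int) -> bool:
        """True if the bond after 0-based position ``i`` is cleaved."""
        if sequence[i] not in self.p1:
            return False
        nxt = sequence[i + 1] if i + 1 < len(sequence) else ""
        return nxt not in self.p1_exclusion


TRYPSIN = CleavageRule("trypsin", frozenset("KR"), frozenset("P"))
CHYMOTRYPSIN = CleavageRule("chymotrypsin", frozenset("FYW"), frozenset("P"))
PEPSIN = CleavageRule("pepsin", frozenset("FL"), frozenset("P"))

ENZYMES = {r.name: r for r in (TRYPSIN, CHYMOTRYPSIN, PEPSIN)}
#: The simulated gastrointestinal cocktail used for gluten protein types.
GASTROINTESTINAL = (PEPSIN, TRYPSIN, CHYMOTRYPSIN)


@dataclass(frozen=True)
class Peptide:
    """A digestion product with provenance in its parent protein.

    ``start``/``end`` are 1-based inclusive positions in the parent;
    ``n_specific``/``c_specific`` flag whether each terminus coincides with a
    cleavage site (or the protein terminus).
    """

    sequence: str
    protein_id: str = ""
    start: int = 1
    end: int = 0
    missed_cleavages: int = 0
    n_specific: bool = True
    c_specific: bool = True

    def __post_init__(self):
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)

    @property
    def semi_specific(self) -> bool:
        return not (self.n_specific and self.c_specific)

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(sequence: str, rules: Iterable[CleavageRule]) -> list[int]:
    """0-based bond indices: a site ``i`` means cleavage between ``i`` and ``i+1``."""
    rules = list(rules)
    if not rules:
        raise DigestionError("empty cleavage rule set")
    sites = []
    for i in range(len(sequence) - 1):
        if any(rule.cuts_after(sequence, i) for rule in rules):
            sites.append(i)
    return sites


def digest(
    protein: str,
    enzymes: Iterable[CleavageRule] | CleavageRule,
    max_missed: int = 2,
    specificity: str = "full",
    protein_id: str = "",
    min_length: int = 1,
    max_length: int | None = None,
) -> list[Peptide]:
    """All digestion products of ``protein`` under the union of the given rules.

    ``specificity="semi"`` additionally yields peptides specific at exactly one
    terminus (the other terminus anywhere), as needed for products of unspecific
    cleavage.  Internal (missed) sites are counted against the combined site set.
    """
    if not protein:
        raise DigestionError("empty protein sequence")
    if max_missed < 0:
        raise DigestionError("max_missed must be >= 0")
    if isinstance(enzymes, CleavageRule):
        enzymes = [enzymes]
    if specificity not in ("full", "semi"):
        raise DigestionError(f"unknown specificity {specificity!r}")

    sites = cleavage_sites(protein, enzymes)
    site_set = set(sites)
    n = len(protein)
    # boundaries as 0-based start offsets: 0, site+1..., n marks the end
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [n]  # exclusive end offsets

    def n_internal(a: int, b: int) -> int:
        """Sites strictly inside the [a, b) slice."""
        return sum(1 for s in site_set if a <= s < b - 1)

    def keep(a: int, b: int) -> bool:
        length = b - a
        if length < min_length:
            return False
        if max_length is not None and length > max_length:
            return False
        return True

    out: dict[tuple[int, int, bool, bool], Peptide] = {}

    def emit(a: int, b: int, n_spec: bool, c_spec: bool) -> None:
        mc = n_internal(a, b)
        if mc > max_missed or not keep(a, b):
            return
        key = (a, b, n_spec, c_spec)
        if key not in out:
            out[key] = Peptide(
                sequence=protein[a:b],
                protein_id=protein_id,
                start=a + 1,
                end=b,
                missed_cleavages=mc,
                n_specific=n_spec,
                c_specific=c_spec,
            )

    for a in starts:
        for b in ends:
            if b > a:
                emit(a, b, True, True)

    if specificity == "semi":
        start_set, end_set = set(starts), set(ends)
        for a in starts:
            for b in range(a + 1, n + 1):
                if b not in end_set:
                    emit(a, b, True, False)
        for b in ends:
            for a in range(0, b):
                if a not in start_set:
                    emit(a, b, False, True)

    # prefer the fully-specific record when the same span arises both ways
    dedup: dict[tuple[int, int], Peptide] = {}
    for pep in sorted(
        out.values(), key=lambda p: (p.start, p.end, not p.n_specific, not p.c_specific)
    ):
        dedup.setdefault((pep.start, pep.end), pep)
    return sorted(dedup.values(), key=lambda p: (p.start, p.end))


#: The seven single-lysine tryptic TG2 peptides used as crosslink donors,
#: keyed by the lysine residue they contribute (TG2 numbering).
DONOR_LYSINES: dict[str, str] = {
    "FLKNAGR": "K205",
    "WKNHGCQR": "K265",
    "ISTKSVGR": "K429",
    "LAEKEETGMAMR": "K468",
    "DLYLENPEIKIR": "K590",
    "QKR": "K600",
    "AVKGFR": "K677",
}

STUDY_DONOR_PEPTIDES: tuple[str, ...] = tuple(DONOR_LYSINES)


def tg2_donor_peptides(
    tg2_sequence: str,
    max_missed: int = 1,
    protein_id: str = "TG2",
) -> list[Peptide]:
    """Tryptic TG2 peptides containing exactly one lysine.

    Single-lysine peptides pin the crosslink acceptor site on the TG2 side,
    removing positional ambiguity from that half of the isopeptide.
    """
    if not tg2_sequence:
        return []
    peptides = digest(tg2_sequence, TRYPSIN, max_missed=max_missed, protein_id=protein_id)
    return [p for p in peptides if p.sequence.count("K") == 1]


def study_donor_subset(donors: Sequence[Peptide]) -> list[Peptide]:
    """The named seven-peptide subset used throughout the study, in K-order."""
    by_seq = {p.sequence: p for p in donors}
    return [by_seq[s] for s in STUDY_DONOR_PEPTIDES if s in by_seq]
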