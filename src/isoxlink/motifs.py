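"""Transglutaminase glutamine-context (Q-motif) bookkeeping.

TG2's sequence specificity is read from the residues following a glutamine:
QXP and QXXF(Y/W/M/L/I/V) — and the more specific QXPF(Y/W/M/L/I/V) — are
preferred deamidation targets, while QP and QXXP are poor or non-targets
(X is any residue except proline).  This module classifies the context of
crosslinked and deamidated glutamines within the peptide as printed and
tabulates counts per motif class and site kind.

Classification precedence is fixed for determinism:
QP → QXPF* → QXP → QXXF* → QXXP → other.  QP and QXP cannot overlap (X ≠ P);
the precedence matters only for QXPF* vs QXP, resolved toward the more
specific QXPF*.  Because QXPF* sites also satisfy the QXP pattern (+2 is P),
summaries additionally report a "QXP family" rollup = QXP + QXPF*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FSTAR_RESIDUES",
    "MOTIF_LABELS",
    "QContext",
    "classify_glutamine_context",
    "motif_summary",
]

#: The aromatic/aliphatic set completing the QXXF-type motifs.
FSTAR_RESIDUES = frozenset("FYWMLIV")

MOTIF_LABELS = ("QP", "QXPF*", "QXP", "QXXF*", "QXXP", "other", "insufficient-context")

#: Labels whose +2 residue is proline — the preferred "QXP" family.
QXP_FAMILY = ("QXP", "QXPF*")


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class QContext:
    """A glutamine and its following residues (+1..+3; None past the C-terminus)."""

    sequence: str
    q_pos: int  # 1-based

    def __post_init__(self):
        if not (1 <= self.q_pos <= len(self.sequence)) or self.sequence[self.q_pos - 1] != "Q":
            raise MotifError(
                f"position {self.q_pos} of {self.sequence!r} is not a glutamine"
            )

    def following(self) -> tuple[str | None, str | None, str | None]:
        tail = self.sequence[self.q_pos:self.q_pos + 3]
        return tuple(tail[i] if i < len(tail) else None for i in range(3))


def classify_glutamine_context(sequence: str, q_pos: int) -> str:
    """Motif label of the glutamine at ``q_pos`` (1-based) within ``sequence``.

    Returns one of :data:`MOTIF_LABELS`; ``insufficient-context`` when the
    peptide ends before any rule can fire.
    """
    f1, f2, f3 = QContext(sequence, q_pos).following()
    if f1 == "P":
        return "QP"
    if f1 is None:
        return "insufficient-context"
    if f2 == "P":
        if f3 in FSTAR_RESIDUES:
            return "QXPF*"
        return "QXP"
    if f2 is None:
        return "insufficient-context"
    if f3 is None:
        return "insufficient-context"
    if f3 in FSTAR_RESIDUES:
        return "QXXF*"
    if f3 == "P":
        return "QXXP"
    return "other"


def motif_summary(records: Iterable) -> pd.DataFrame:
    """Motif-label × site-kind contingency over isopeptide records.

    ``records`` need attributes ``gluten_peptide``, ``crosslink_q`` (None when
    ambiguous), ``deamidation`` (sequence of positions), and optionally
    ``crosslink_ambiguous`` / ``deamidation_ambiguous`` (sequences of
    candidate positions).  Unambiguous sites populate the per-label counts;
    ambiguous sites are tallied separately in the ``ambiguous`` row.  A
    ``QXP-family`` row aggregates QXP + QXPF*.
    """
    counts = {label: {"crosslink": 0, "deamidation": 0} for label in MOTIF_LABELS}
    ambiguous = {"crosslink": 0, "deamidation": 0}
    for rec in records:
        seq = rec.gluten_peptide
        if getattr(rec, "crosslink_q", None):
            label = classify_glutamine_context(seq, rec.crosslink_q)
            counts[label]["crosslink"] += 1
        elif getattr(rec, "crosslink_ambiguous", ()):
            ambiguous["crosslink"] += 1
        for pos in getattr(rec, "deamidation", ()) or ():
            label = classify_glutamine_context(seq, pos)
            counts[label]["deamidation"] += 1
        if getattr(rec, "deamidation_ambiguous", ()):
            ambiguous["deamidation"] += 1
    rows = {label: counts[label] for label in MOTIF_LABELS}
    rows["QXP-family"] = {
        kind: sum(counts[l][kind] for l in QXP_FAMILY) for kind in ("crosslink", "deamidation")
    }
    rows["ambiguous"] = ambiguous
    df = pd.DataFrame(rows).T
    df.index.name = "motif"
    return df
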