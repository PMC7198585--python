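"""Packaged reference data: the 29-isopeptide result set and carrier sequences.

The isopeptide table transcribes the study's identified crosslinks between
gluten peptides of wheat (W1–W13), rye (R1–R6) and barley (B1–B10) and the
seven single-lysine tryptic TG2 peptides.  Site annotations follow the
localization evidence (figures and the motif groupings discussed by id);
records where the typeset table is internally inconsistent carry a note.
The TG2 carrier sequence shipped here is a synthetic stand-in (see the FASTA
header) that reproduces the seven donor peptides at the published lysine
positions; it is sufficient for digestion and donor-selection logic but is
not the native protein elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

from .digestion import DONOR_LYSINES, STUDY_DONOR_PEPTIDES

__all__ = [
    "PaperIsopeptideRecord",
    "load_paper_isopeptides",
    "load_tg2_sequence",
    "read_fasta",
]


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class PaperIsopeptideRecord:
    """One transcribed isopeptide with site annotations and provenance."""

    id: str
    grain: str
    gpt: str
    tg2_lysine: str
    tg2_peptide: str
    gluten_peptide: str
    crosslink_q: int | None
    crosslink_ambiguous: tuple[int, ...]
    deamidation: tuple[int, ...]
    deamidation_ambiguous: tuple[int, ...]
    accession: str
    protein_name: str
    organism: str
    mq_score: float
    prm_localized: bool
    unspecific_cleavage: bool
    note: str = ""

    @property
    def beta_k_pos(self) -> int:
        return self.tg2_peptide.index("K") + 1


def _parse_positions(cell) -> tuple[int, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    return tuple(int(x) for x in str(cell).replace("|", ";").split(";"))


def _data_path(name: str):
    return resources.files("isoxlink").joinpath("data", name)


def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines allowed) → {identifier: sequence}."""
    from Bio import SeqIO

    with open(path) as handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def load_tg2_sequence() -> str:
    """The packaged TG2 carrier sequence (synthetic stand-in, 687 aa)."""
    with resources.as_file(_data_path("tg2_p21980_synthetic.fasta")) as path:
        records = read_fasta(path)
    (seq,) = records.values()
    return seq


def load_paper_isopeptides(validate: bool = True) -> list[PaperIsopeptideRecord]:
    """All 29 transcribed isopeptide records, invariant-checked."""
    with resources.as_file(_data_path("isopeptides.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        xq = _parse_positions(row["xlink_q"])
        records.append(
            PaperIsopeptideRecord(
                id=row["id"],
                grain=row["grain"],
                gpt=row["gpt"],
                tg2_lysine=row["tg2_lysine"],
                tg2_peptide=row["tg2_peptide"],
                gluten_peptide=row["gluten_peptide"],
                crosslink_q=xq[0] if xq else None,
                crosslink_ambiguous=_parse_positions(row["xlink_ambiguous"]),
                deamidation=_parse_positions(row["deamidation"]),
                deamidation_ambiguous=_parse_positions(row["deam_ambiguous"]),
                accession=row["accession"],
                protein_name=row["protein_name"],
                organism=row["organism"],
                mq_score=float(row["mq_score"]),
                prm_localized=row["prm_localized"] == "1",
                unspecific_cleavage=row["unspecific_cleavage"] == "1",
                note=row.get("note", ""),
            )
        )
    if validate:
        _validate(records)
    return records


def _validate(records: list[PaperIsopeptideRecord]) -> None:
    errors: list[str] = []
    if len(records) != 29:
        errors.append(f"expected 29 records, found {len(records)}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        errors.append("duplicate record ids")
    for r in records:
        if r.tg2_peptide not in STUDY_DONOR_PEPTIDES:
            errors.append(f"{r.id}: TG2 peptide {r.tg2_peptide!r} is not one of the seven donors")
        elif DONOR_LYSINES[r.tg2_peptide] != r.tg2_lysine:
            errors.append(f"{r.id}: lysine label {r.tg2_lysine} does not match {r.tg2_peptide}")
        if r.tg2_peptide.count("K") != 1:
            errors.append(f"{r.id}: TG2 peptide must contain exactly one K")
        sites = ([r.crosslink_q] if r.crosslink_q else []) + list(r.crosslink_ambiguous)
        if not sites:
            errors.append(f"{r.id}: no crosslink site recorded")
        for pos in sites:
            if not (1 <= pos <= len(r.gluten_peptide)) or r.gluten_peptide[pos - 1] != "Q":
                errors.append(f"{r.id}: crosslink position {pos} is not a Q")
        for pos in list(r.deamidation) + list(r.deamidation_ambiguous):
            if not (1 <= pos <= len(r.gluten_peptide)) or r.gluten_peptide[pos - 1] not in "NQ":
                errors.append(f"{r.id}: deamidation position {pos} is not N/Q")
        if r.crosslink_q and r.crosslink_q in r.deamidation:
            errors.append(f"{r.id}: deamidation recorded on the crosslinked Q")
        if r.crosslink_ambiguous and not r.note:
            errors.append(f"{r.id}: ambiguous crosslink without a note")
    amb_x = sorted(r.id for r in records if r.crosslink_ambiguous)
    amb_d = sorted(r.id for r in records if r.deamidation_ambiguous)
    if amb_x != ["B4", "B6"]:
        errors.append(f"ambiguous-crosslink ids {amb_x} != ['B4', 'B6']")
    if amb_d != ["B6", "B8"]:
        errors.append(f"ambiguous-deamidation ids {amb_d} != ['B6', 'B8']")
    if errors:
        raise FixtureError("fixture validation failed:\n  " + "\n  ".join(errors))
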