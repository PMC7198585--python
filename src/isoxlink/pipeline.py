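"""End-to-end orchestration: reciprocal discovery runs, grouping, confirmation.

One discovery search is executed per TG2 donor peptide (the active crosslink
modification) per run; rank-1 identifications are grouped into molecule keys
(α sequence, β sequence, crosslink site, deamidation set) and pooled across
the run design into per-replicate evidence, to which the confirmation rule
set is applied.  This is the programmatic equivalent of the CLI's
simulate → search → validate chain and the entry point used by benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem import isotope_abundances
from .isopeptide import Isopeptide, composition as iso_composition
from .search import SearchConfig, Spectrum, SpectrumMatch, run_discovery_search
from .validate import (
    ConfirmationRecord,
    ConfirmationThresholds,
    ReplicateEvidence,
    RunDesign,
    apply_confirmation,
    idotp,
)

logger = logging.getLogger("isoxlink")

__all__ = ["MoleculeKey", "discover_and_confirm", "benchmark_against_manifest"]


@dataclass(frozen=True, order=True)
class MoleculeKey:
    """Identity of a site-resolved isopeptide, independent of spectrum or run."""

    alpha: str
    beta: str
    alpha_q_pos: int
    deamidation: tuple[int, ...]

    @classmethod
    def of(cls, iso: Isopeptide) -> "MoleculeKey":
        return cls(iso.alpha_seq, iso.beta_seq, iso.alpha_q_pos, iso.deamidation)


def _match_idotp(match: SpectrumMatch, spectrum: Spectrum) -> float | None:
    env = spectrum.precursor_envelope
    if env is None:
        return None
    expected = isotope_abundances(iso_composition(match.isopeptide), len(env))
    return idotp(expected, env)


def discover_and_confirm(
    runs: Mapping[str, Sequence[Spectrum]],
    proteins: Mapping[str, str],
    donor_peptides: Sequence[str],
    design: RunDesign,
    search_config: SearchConfig | None = None,
    thresholds: ConfirmationThresholds | None = None,
) -> dict[MoleculeKey, ConfirmationRecord]:
    """Reciprocal discovery over all donors and runs, then confirmation.

    Returns one confirmation record per molecule key seen at rank 1 in any
    sample replicate.
    """
    config = search_config or SearchConfig()
    spectra_by_scan: dict[str, Spectrum] = {}
    for run_id, spectra in runs.items():
        for s in spectra:
            spectra_by_scan[s.scan_id] = s
    # reciprocal runs: one search per donor modification; per spectrum, only the
    # best-scoring rank-1 across all donors is retained
    best_by_scan: dict[tuple[str, str], SpectrumMatch] = {}
    for donor in donor_peptides:
        for run_id, spectra in runs.items():
            for match in run_discovery_search(spectra, proteins, donor, config):
                if match.rank != 1:
                    continue
                key = (run_id, match.scan_id)
                cur = best_by_scan.get(key)
                if cur is None or match.score > cur.score:
                    best_by_scan[key] = match
    rank1: dict[str, list[tuple[SpectrumMatch, Spectrum]]] = {r: [] for r in runs}
    for (run_id, scan_id), match in best_by_scan.items():
        rank1[run_id].append((match, spectra_by_scan[scan_id]))

    keys = sorted(
        {
            MoleculeKey.of(m.isopeptide)
            for r in design.samples
            for m, _ in rank1.get(r, [])
        }
    )
    out: dict[MoleculeKey, ConfirmationRecord] = {}
    for key in keys:
        evidence: dict[str, ReplicateEvidence] = {}
        localization = 0.0
        best_score = -1.0
        iso = None
        for rep in design.samples:
            hits = [
                (m, s) for m, s in rank1.get(rep, []) if MoleculeKey.of(m.isopeptide) == key
            ]
            if not hits:
                continue
            match, spectrum = max(hits, key=lambda t: t[0].score)
            evidence[rep] = ReplicateEvidence(
                replicate_id=rep,
                retention_time=match.retention_time,
                score=match.score,
                matched_fragments=match.matched_fragments,
                idotp=_match_idotp(match, spectrum),
            )
            if match.score > best_score:
                best_score = match.score
                localization = match.localization_probability
                iso = match.isopeptide
        control_detections = tuple(
            rep for rep in design.controls
            if any(MoleculeKey.of(m.isopeptide) == key for m, _ in rank1.get(rep, []))
        )
        out[key] = apply_confirmation(
            evidence=evidence,
            design=design,
            localization_probability=localization,
            control_detections=control_detections,
            thresholds=thresholds,
            isopeptide=iso,
        )
    return out


def benchmark_against_manifest(
    records: Mapping[MoleculeKey, ConfirmationRecord],
    manifest,
) -> dict[str, float]:
    """Sensitivity/specificity of the confirmed set against simulated truth.

    Sensitivity = confirmed true isopeptides / injected isopeptides;
    specificity = 1 − (confirmed molecules not in the manifest / confirmed
    molecules), i.e. the fraction of confirmations that are true.
    """
    truth_keys = {MoleculeKey.of(t.isopeptide) for t in manifest.isopeptides}
    confirmed = {k for k, rec in records.items() if rec.verdict == "confirmed"}
    tp = len(confirmed & truth_keys)
    sensitivity = tp / len(truth_keys) if truth_keys else float("nan")
    specificity = tp / len(confirmed) if confirmed else 1.0
    return {
        "n_true": len(truth_keys),
        "n_confirmed": len(confirmed),
        "true_positives": tp,
        "sensitivity": sensitivity,
        "specificity": specificity,
    }
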