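"""Replicate/negative-control confirmation of discovery identifications.

An isopeptide identification is confirmed only when, across the declared run
design, it is (a) detected in every sample replicate with consistent retention
times, (b) absent from every negative control, (c) supported by at least seven
matched b/y fragments, (d) among them at least three consecutive in one ion
ladder, (e) has a precursor isotope dot product (idotp) above 0.9, and (f) has
its crosslink site localized with probability above 0.75 — otherwise the
verdict is "ambiguous-site" rather than "confirmed".  Every failed criterion
is reported as an explicit reason code, so a verdict is a pure, auditable
function of the evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .isopeptide import Isopeptide, TheoreticalFragment

__all__ = [
    "ConfirmationThresholds",
    "ReplicateEvidence",
    "RunDesign",
    "ConfirmationRecord",
    "max_consecutive_series",
    "idotp",
    "apply_confirmation",
]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class ConfirmationThresholds:
    """Decision thresholds; defaults follow the confirmation rule set."""

    min_by_fragments: int = 7
    min_consecutive: int = 3
    min_localization: float = 0.75
    min_idotp: float = 0.9
    rt_tolerance_min: float = 0.5
    required_replicates: int | None = None  # None = all sample replicates


@dataclass(frozen=True)
class RunDesign:
    """Sample/control replicate labels for one experiment."""

    samples: tuple[str, ...]
    controls: tuple[str, ...]

    def __post_init__(self):
        if not self.samples:
            raise DesignError("run design needs at least one sample replicate")
        if not self.controls:
            raise DesignError("run design needs at least one negative control")


@dataclass
class ReplicateEvidence:
    """Per-replicate evidence for one isopeptide."""

    replicate_id: str
    retention_time: float
    score: float
    matched_fragments: Sequence[TheoreticalFragment] = ()
    n_by_fragments: int | None = None
    max_consecutive: int | None = None
    idotp: float | None = None

    def by_fragment_count(self) -> int:
        if self.n_by_fragments is not None:
            return self.n_by_fragments
        # unique (side, type, index) b/y ions; charge and loss variants collapse
        return len(
            {
                (f.side, f.ion_type, f.index)
                for f in self.matched_fragments
                if f.ion_type in ("b", "y")
            }
        )

    def consecutive(self) -> int:
        if self.max_consecutive is not None:
            return self.max_consecutive
        return max_consecutive_series(self.matched_fragments)


@dataclass
class ConfirmationRecord:
    """Verdict plus reason codes for one isopeptide under one run design."""

    isopeptide: Isopeptide | None
    verdict: str  # "confirmed" | "ambiguous-site" | "rejected"
    reasons: tuple[str, ...]
    evidence: dict[str, ReplicateEvidence]
    control_detections: tuple[str, ...]
    localization_probability: float


def max_consecutive_series(fragments: Iterable[TheoreticalFragment]) -> int:
    """Longest run of consecutive ladder indices within one (side, ion-type) ladder.

    Loss variants and charge states collapse onto the same index; runs never
    join different ladders (e.g. b and y, or α and β).
    """
    ladders: dict[tuple[str, str], set[int]] = {}
    for f in fragments:
        if f.ion_type == "internal":
            continue
        ladders.setdefault((f.side, f.ion_type), set()).add(f.index)
    best = 0
    for indices in ladders.values():
        run = 0
        prev = None
        for i in sorted(indices):
            run = run + 1 if prev is not None and i == prev + 1 else 1
            prev = i
            best = max(best, run)
    return best


def idotp(expected: Sequence[float], observed: Sequence[float]) -> float:
    """Normalized dot product (cosine) of expected vs observed isotope envelopes."""
    e = np.asarray(expected, dtype=float)
    o = np.asarray(observed, dtype=float)
    if e.shape != o.shape or e.size < 2:
        raise ValueError("expected/observed must have equal length >= 2")
    if np.any(o < 0):
        raise ValueError("observed intensities must be non-negative")
    no = np.linalg.norm(o)
    ne = np.linalg.norm(e)
    if no == 0:
        raise ValueError("observed envelope is all zero")
    if ne == 0:
        raise ValueError("expected envelope is all zero")
    return float(np.dot(e, o) / (ne * no))


def apply_confirmation(
    evidence: Mapping[str, ReplicateEvidence],
    design: RunDesign,
    localization_probability: float,
    control_detections: Sequence[str] = (),
    thresholds: ConfirmationThresholds | None = None,
    isopeptide: Isopeptide | None = None,
) -> ConfirmationRecord:
    """Apply the confirmation rule set to one isopeptide's pooled evidence.

    ``evidence`` maps sample replicate id → evidence (absent id = not
    detected); ``control_detections`` lists negative-control replicates in
    which the species was detected.
    """
    th = thresholds or ConfirmationThresholds()
    unknown = set(evidence) - set(design.samples)
    if unknown:
        raise DesignError(f"evidence for undeclared replicates: {sorted(unknown)}")

    reasons: list[str] = []
    detected = [r for r in design.samples if r in evidence]
    required = th.required_replicates or len(design.samples)
    if len(detected) < required:
        reasons.append("replicate-detection")
    if any(c in control_detections for c in design.controls):
        reasons.append("negative-control")

    if detected:
        rts = [evidence[r].retention_time for r in detected]
        if max(rts) - min(rts) > th.rt_tolerance_min:
            reasons.append("retention-time")
        if min(ev.by_fragment_count() for ev in evidence.values()) < th.min_by_fragments:
            reasons.append("min-fragments")
        if min(ev.consecutive() for ev in evidence.values()) < th.min_consecutive:
            reasons.append("consecutive-series")
        idotps = [ev.idotp for ev in evidence.values() if ev.idotp is not None]
        if idotps and min(idotps) <= th.min_idotp:
            reasons.append("idotp")
    else:
        reasons.append("min-fragments")

    if reasons:
        verdict = "rejected"
    elif localization_probability <= th.min_localization:
        verdict = "ambiguous-site"
        reasons.append("localization")
    else:
        verdict = "confirmed"

    return ConfirmationRecord(
        isopeptide=isopeptide,
        verdict=verdict,
        reasons=tuple(reasons),
        evidence=dict(evidence),
        control_detections=tuple(control_detections),
        localization_probability=localization_probability,
    )
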