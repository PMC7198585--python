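"""Targeted (PRM) validation of isopeptides.

Confirmed or ambiguous discovery identifications are exported as an isolation
list carrying both representations of each isopeptide — the gluten peptide as
base with the TG2 peptide as modification (α-base) and the reverse (β-base).
Unscheduled PRM runs are then analysed by collecting, per target, the MS2
scans whose isolation window covers the precursor, extracting per-transition
intensity traces over time, picking elution peaks, and applying the targeted
confirmation rules: at least seven co-eluting b/y transitions, at least three
consecutive in one ladder, retention time consistent with discovery, precursor
idotp above threshold where precursor traces exist, and no signal in the
negative controls.  Site-determining transitions present for one candidate
site and absent for the alternatives assign the crosslink/deamidation site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import mz_from_mass
from .isopeptide import (
    FragmentConfig,
    Isopeptide,
    TheoreticalFragment,
    enumerate_fragments,
    precursor_mass,
    precursor_mz,
)
from .search import Spectrum
from .validate import ConfirmationThresholds, DesignError, RunDesign, max_consecutive_series

__all__ = [
    "PrmTarget",
    "Chromatogram",
    "build_isolation_list",
    "isolation_list_table",
    "write_isolation_list",
    "read_isolation_list",
    "extract_chromatograms",
    "prm_confirm",
    "PrmVerdict",
]

ISOLATION_COLUMNS = ["m/z", "charge", "polarity", "start", "end", "name"]


@dataclass
class PrmTarget:
    """One precursor (isopeptide × representation × charge) with its transitions."""

    isopeptide_id: str
    isopeptide: Isopeptide
    representation: str  # "alpha-base" | "beta-base"
    precursor_mz: float
    charge: int
    transitions: list[TheoreticalFragment] = field(default_factory=list)
    expected_rt: float | None = None

    @property
    def name(self) -> str:
        return f"{self.isopeptide_id}|{self.representation}|z{self.charge}"


def _transitions(iso: Isopeptide, representation: str, config: FragmentConfig):
    side = "alpha" if representation == "alpha-base" else "beta"
    return enumerate_fragments(iso, config, sides=(side,))


def build_isolation_list(
    isopeptides: Mapping[str, Isopeptide],
    charges: Sequence[int] = (2, 3),
    fragment_config: FragmentConfig | None = None,
    expected_rt: Mapping[str, float] | None = None,
) -> list[PrmTarget]:
    """One target per (isopeptide, representation, precursor charge), duplicates collapsed."""
    if not isopeptides:
        raise ValueError("need at least one isopeptide")
    config = fragment_config or FragmentConfig(max_charge=1)
    targets: dict[str, PrmTarget] = {}
    for iso_id in sorted(isopeptides):
        iso = isopeptides[iso_id]
        for representation in ("alpha-base", "beta-base"):
            trans = _transitions(iso, representation, config)
            for z in charges:
                t = PrmTarget(
                    isopeptide_id=iso_id,
                    isopeptide=iso,
                    representation=representation,
                    precursor_mz=precursor_mz(iso, z),
                    charge=z,
                    transitions=trans,
                    expected_rt=(expected_rt or {}).get(iso_id),
                )
                targets.setdefault(t.name, t)
    return list(targets.values())


def isolation_list_table(targets: Sequence[PrmTarget], window: float = 1.7) -> pd.DataFrame:
    """Vendor-neutral isolation list: (m/z, charge, polarity, start, end, name)."""
    rows = [
        {
            "m/z": round(t.precursor_mz, 4),
            "charge": t.charge,
            "polarity": "Positive",
            "start": round(t.precursor_mz - window / 2, 4),
            "end": round(t.precursor_mz + window / 2, 4),
            "name": t.name,
        }
        for t in targets
    ]
    return pd.DataFrame(rows, columns=ISOLATION_COLUMNS)


def write_isolation_list(targets: Sequence[PrmTarget], path: str, window: float = 1.7) -> None:
    isolation_list_table(targets, window).to_csv(path, sep="\t", index=False)


def read_isolation_list(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ISOLATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"isolation list missing columns: {sorted(missing)}")
    return df


@dataclass
class Chromatogram:
    """Per-transition intensity trace with a picked elution peak."""

    target_name: str
    transition: TheoreticalFragment | None  # None = precursor trace
    times: np.ndarray
    intensities: np.ndarray
    peak_start: float | None = None
    peak_apex: float | None = None
    peak_end: float | None = None
    area: float = 0.0

    @property
    def detected(self) -> bool:
        return self.peak_apex is not None and self.area > 0


def _pick_peak(times: np.ndarray, trace: np.ndarray):
    """Maximal contiguous region above baseline, bounded at 5% of apex height.

    Baseline = median of the trace; deterministic and parameter-free, chosen
    because targeted data here are analysed without interactive curation.
    """
    if len(times) == 0 or trace.max() <= 0:
        return None
    baseline = float(np.median(trace))
    apex_i = int(np.argmax(trace))
    apex_height = trace[apex_i] - baseline
    if apex_height <= 0:
        return None
    cutoff = baseline + 0.05 * apex_height
    lo = apex_i
    while lo > 0 and trace[lo - 1] > cutoff:
        lo -= 1
    hi = apex_i
    while hi < len(trace) - 1 and trace[hi + 1] > cutoff:
        hi += 1
    if hi == lo:
        return None
    area = float(np.trapezoid(trace[lo:hi + 1] - baseline, times[lo:hi + 1]))
    return float(times[lo]), float(times[apex_i]), float(times[hi]), max(area, 0.0)


def extract_chromatograms(
    spectra: Sequence[Spectrum],
    targets: Sequence[PrmTarget],
    fragment_tol: float = 0.5,
    include_precursor: bool = False,
) -> dict[str, list[Chromatogram]]:
    """Per-target transition traces from unscheduled PRM MS2 scans.

    A scan contributes to a target when its isolation window (centre =
    precursor m/z, declared width) contains the target precursor.  The
    per-transition intensity of a scan is the summed intensity of its peaks
    within ``fragment_tol`` of the transition m/z.
    """
    if fragment_tol <= 0:
        raise ValueError("fragment tolerance must be positive")
    out: dict[str, list[Chromatogram]] = {}
    ordered = sorted(spectra, key=lambda s: s.retention_time)
    for target in targets:
        scans = [
            s for s in ordered
            if abs(s.precursor_mz - target.precursor_mz) <= s.isolation_width / 2
        ]
        times = np.array([s.retention_time for s in scans])
        chroms = []
        for trans in target.transitions:
            trace = np.zeros(len(scans))
            for i, s in enumerate(scans):
                lo = np.searchsorted(s.mz, trans.mz - fragment_tol, side="left")
                hi = np.searchsorted(s.mz, trans.mz + fragment_tol, side="right")
                trace[i] = s.intensity[lo:hi].sum()
            chrom = Chromatogram(target.name, trans, times, trace)
            picked = _pick_peak(times, trace)
            if picked:
                chrom.peak_start, chrom.peak_apex, chrom.peak_end, chrom.area = picked
            chroms.append(chrom)
        out[target.name] = chroms
    return out


@dataclass
class PrmVerdict:
    isopeptide_id: str
    verdict: str  # "confirmed" | "rejected"
    reasons: tuple[str, ...]
    n_coeluting_by: int
    max_consecutive: int
    apex_rt: float | None
    assigned_site: int | None = None


def _coeluting(chroms: Sequence[Chromatogram], rt_window: float):
    """Detected transitions whose apex lies within rt_window of the modal apex."""
    detected = [c for c in chroms if c.detected]
    if not detected:
        return [], None
    apexes = np.array([c.peak_apex for c in detected])
    # modal apex = apex of the strongest transition
    anchor = detected[int(np.argmax([c.area for c in detected]))].peak_apex
    kept = [c for c in detected if abs(c.peak_apex - anchor) <= rt_window]
    return kept, float(anchor)


def prm_confirm(
    chromatograms_by_replicate: Mapping[str, Sequence[Chromatogram]],
    design: RunDesign,
    expected_rt: float | None = None,
    precursor_idotp: Mapping[str, float] | None = None,
    site_determining: Mapping[int, Sequence[str]] | None = None,
    thresholds: ConfirmationThresholds | None = None,
    isopeptide_id: str = "",
    coelution_window: float = 0.2,
) -> PrmVerdict:
    """Apply the targeted confirmation rules to one isopeptide.

    ``chromatograms_by_replicate`` maps replicate id (samples and controls) to
    that replicate's transition traces.  ``site_determining`` maps candidate
    site → labels of transitions that pin that site; the site whose
    determining transitions are all detected (and uniquely so) is assigned.
    """
    th = thresholds or ConfirmationThresholds()
    missing_controls = [c for c in design.controls if c not in chromatograms_by_replicate]
    if missing_controls:
        raise DesignError(f"controls without PRM data: {missing_controls}")

    reasons: list[str] = []
    per_rep_counts: list[int] = []
    per_rep_consec: list[int] = []
    apexes: list[float] = []

    for rep in design.samples:
        chroms = chromatograms_by_replicate.get(rep, [])
        kept, anchor = _coeluting(chroms, coelution_window)
        by = [c for c in kept if c.transition and c.transition.ion_type in ("b", "y")]
        per_rep_counts.append(
            len({(c.transition.side, c.transition.ion_type, c.transition.index) for c in by})
        )
        per_rep_consec.append(max_consecutive_series([c.transition for c in by]))
        if anchor is not None:
            apexes.append(anchor)

    n_by = min(per_rep_counts) if per_rep_counts else 0
    consec = min(per_rep_consec) if per_rep_consec else 0
    if len(apexes) < len(design.samples):
        reasons.append("replicate-detection")
    if n_by < th.min_by_fragments:
        reasons.append("min-fragments")
    if consec < th.min_consecutive:
        reasons.append("consecutive-series")
    if apexes and (max(apexes) - min(apexes)) > th.rt_tolerance_min:
        reasons.append("retention-time")
    if apexes and expected_rt is not None:
        if abs(float(np.median(apexes)) - expected_rt) > th.rt_tolerance_min:
            reasons.append("retention-time-vs-discovery")
    if precursor_idotp:
        vals = [precursor_idotp[r] for r in design.samples if r in precursor_idotp]
        if vals and min(vals) <= th.min_idotp:
            reasons.append("idotp")
    for control in design.controls:
        kept, _ = _coeluting(chromatograms_by_replicate.get(control, []), coelution_window)
        if kept:
            reasons.append("negative-control")
            break

    assigned = None
    if site_determining:
        hits = {}
        for site, labels in site_determining.items():
            labels = set(labels)
            found = set()
            for rep in design.samples:
                for c in chromatograms_by_replicate.get(rep, []):
                    if c.detected and c.transition and c.transition.label in labels:
                        found.add(c.transition.label)
            hits[site] = labels <= found and bool(labels)
        winners = [s for s, ok in hits.items() if ok]
        if len(winners) == 1:
            assigned = winners[0]

    verdict = "rejected" if reasons else "confirmed"
    return PrmVerdict(
        isopeptide_id=isopeptide_id,
        verdict=verdict,
        reasons=tuple(reasons),
        n_coeluting_by=n_by,
        max_consecutive=consec,
        apex_rt=float(np.median(apexes)) if apexes else None,
        assigned_site=assigned,
    )
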