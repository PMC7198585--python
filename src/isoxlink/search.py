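"""Discovery-mode identification of isopeptides from MS/MS spectra.

Candidate α-side (gluten) peptides come from an in-silico digest of the
supplied protein database; one TG2 donor peptide at a time acts as the active
crosslink modification (reciprocal runs iterate over the seven donors).  A
spectrum's candidates are peptides whose mass plus the crosslink-modification
mass plus any deamidation deltas matches the precursor within a ppm tolerance;
each candidate is expanded over admissible crosslink/deamidation placements,
scored against the spectrum, and ranked.

Scoring is an explicit binomial survival score: with ``t`` theoretical
fragments, ``m`` of them matched, and a per-fragment chance-match probability
``p`` estimated from the spectrum's peak density, the score is
``−10·log10 P(X ≥ m)`` for ``X ~ Binomial(t, p)``.  This is a transparent
surrogate for proprietary engine scores — comparable within a run, not on the
engine's scale.  Site-localization probabilities are a softmax of
``10^(score/10)`` over alternative placements, with sites above 0.75 flagged
localized, in line with published PTM-scoring practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .chem import PROTON_MASS, monoisotopic_mass, peptide_mass, xlink_modification_composition
from .digestion import GASTROINTESTINAL, CleavageRule, Peptide, digest
from .isopeptide import (
    DEAMIDATION_MASS,
    FragmentConfig,
    Isopeptide,
    TheoreticalFragment,
    count_fragment_matches,
    enumerate_fragments,
    fragment_mz_array,
    match_fragments,
    precursor_mass,
)

logger = logging.getLogger("isoxlink")

__all__ = [
    "Spectrum",
    "SearchConfig",
    "SpectrumMatch",
    "run_discovery_search",
    "score_match",
    "localize_sites",
    "read_spectra",
]


@dataclass
class Spectrum:
    """A centroided MS2 spectrum with precursor metadata."""

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    retention_time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    isolation_width: float = 1.7
    precursor_envelope: np.ndarray | None = None  # observed precursor isotope envelope

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def neutral_mass(self) -> float:
        return self.precursor_mz * self.precursor_charge - self.precursor_charge * PROTON_MASS


def read_spectra(path: str) -> list[Spectrum]:
    """Read centroided MS2 spectra from an MGF or mzML file (by extension)."""
    path = str(path)
    if path.lower().endswith(".mgf"):
        return _read_mgf(path)
    if path.lower().endswith(".mzml"):
        return _read_mzml(path)
    raise ValueError(f"unsupported spectrum file {path!r} (expected .mgf or .mzML)")


def _read_mgf(path: str) -> list[Spectrum]:
    from pyteomics import mgf

    out = []
    with mgf.MGF(path) as reader:
        for i, spec in enumerate(reader):
            params = spec["params"]
            try:
                pep = params["pepmass"]
                pre_mz = pep[0] if isinstance(pep, (tuple, list)) else float(pep)
                charge = int(params.get("charge", [2])[0])
                rt = float(params.get("rtinseconds", 0.0)) / 60.0
            except (KeyError, ValueError, TypeError, IndexError) as exc:
                logger.warning("skipping malformed MGF record %d in %s: %s", i, path, exc)
                continue
            out.append(
                Spectrum(
                    scan_id=str(params.get("title", f"scan={i}")),
                    precursor_mz=float(pre_mz),
                    precursor_charge=abs(charge),
                    retention_time=rt,
                    mz=spec["m/z array"],
                    intensity=spec["intensity array"],
                )
            )
    return out


def _read_mzml(path: str) -> list[Spectrum]:
    from pyteomics import mzml

    out = []
    with mzml.MzML(path) as reader:
        for spec in reader:
            if spec.get("ms level") != 2:
                continue
            try:
                precursor = spec["precursorList"]["precursor"][0]
                ion = precursor["selectedIonList"]["selectedIon"][0]
                pre_mz = float(ion["selected ion m/z"])
                charge = int(ion.get("charge state", 2))
                scan = spec["scanList"]["scan"][0]
                rt = float(scan.get("scan start time", 0.0))
                width = float(
                    precursor.get("isolationWindow", {}).get(
                        "isolation window lower offset", 0.85
                    )
                ) * 2
            except (KeyError, ValueError, TypeError, IndexError) as exc:
                logger.warning("skipping malformed mzML spectrum in %s: %s", path, exc)
                continue
            out.append(
                Spectrum(
                    scan_id=str(spec.get("id", "")),
                    precursor_mz=pre_mz,
                    precursor_charge=charge,
                    retention_time=rt,
                    mz=spec["m/z array"],
                    intensity=spec["intensity array"],
                    isolation_width=width,
                )
            )
    return out


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of one discovery run (one active crosslink modification)."""

    precursor_tol_ppm: float = 4.5
    fragment_tol_da: float = 0.5
    max_modifications: int = 5
    min_score_modified: float = 40.0
    max_missed_cleavages: int = 2
    enzymes: tuple[CleavageRule, ...] = tuple(GASTROINTESTINAL)
    specificity: str = "full"
    min_peptide_length: int = 5
    max_peptide_length: int = 30
    max_placements_per_candidate: int = 2000
    fragment_config: FragmentConfig = field(default_factory=FragmentConfig)
    decoy: str = "shuffle"
    seed: int = 0


@dataclass
class SpectrumMatch:
    """One ranked isopeptide candidate for one spectrum."""

    scan_id: str
    retention_time: float
    isopeptide: Isopeptide
    score: float
    rank: int
    matched_fragments: list[TheoreticalFragment]
    n_theoretical: int
    crosslink_site_probs: dict[int, float]
    deamidation_site_probs: dict[int, float]
    is_decoy: bool = False

    @property
    def localization_probability(self) -> float:
        return self.crosslink_site_probs.get(self.isopeptide.alpha_q_pos, 0.0)

    @property
    def localized(self) -> bool:
        return self.localization_probability > 0.75


def _log10_binomial_tail(matched: int, n: int, p: float) -> float:
    """log10 P(X ≥ matched) for X ~ Binomial(n, p), exact in log space.

    Summed with log-sum-exp over the tail terms so deep tails (far beyond
    float underflow of the plain survival function) stay exact; scores must
    keep discriminating between near-complete matches.
    """
    from scipy.special import gammaln, logsumexp

    if matched <= 0:
        return 0.0
    k = np.arange(matched, n + 1)
    logpmf = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * np.log(p) + (n - k) * np.log1p(-p)
    )
    return float(logsumexp(logpmf) / np.log(10.0))


def score_match(
    matched_count: int,
    theoretical_count: int,
    chance_p: float,
) -> float:
    """Binomial survival score ``−10·log10 P(X ≥ matched)``, X ~ B(t, p)."""
    if theoretical_count <= 0:
        raise ValueError("theoretical_count must be positive")
    if not 0 <= matched_count <= theoretical_count:
        raise ValueError("matched_count outside 0..theoretical_count")
    if matched_count == 0:
        return 0.0
    p = min(max(chance_p, 1e-9), 0.999)
    return -10.0 * _log10_binomial_tail(matched_count, theoretical_count, p)


def chance_match_probability(spectrum: Spectrum, tol: float) -> float:
    """Per-fragment probability of a random match: peak density × 2·tol."""
    n = len(spectrum.mz)
    if n == 0:
        return 1e-9
    span = max(float(spectrum.mz[-1] - spectrum.mz[0]), 200.0)
    return min(n * 2.0 * tol / span, 0.3)


def _score_placement(spectrum: Spectrum, iso: Isopeptide, config: SearchConfig):
    frags = enumerate_fragments(iso, config.fragment_config)
    matches = match_fragments(spectrum.mz, spectrum.intensity, frags, config.fragment_tol_da)
    p = chance_match_probability(spectrum, config.fragment_tol_da)
    score = score_match(len(matches), len(frags), p)
    return score, [f for f, _ in matches], len(frags)


def _score_placement_fast(spectrum: Spectrum, iso: Isopeptide, config: SearchConfig) -> float:
    """Score via the numeric fragment-m/z path (no fragment objects)."""
    theor = fragment_mz_array(iso, config.fragment_config)
    matched = count_fragment_matches(
        theor, spectrum.mz, spectrum.intensity, config.fragment_tol_da
    )
    p = chance_match_probability(spectrum, config.fragment_tol_da)
    return score_match(matched, len(theor), p)


def localize_sites(
    spectrum: Spectrum,
    placements: Sequence[Isopeptide],
    config: SearchConfig,
) -> tuple[np.ndarray, dict[int, float], dict[int, float]]:
    """Placement and per-site probabilities for alternative site assignments.

    Placements must be variants of the same peptide pair differing only in
    crosslink/deamidation positions.  Placement weights are a softmax of
    ``10^(score/10)``; a site's probability is the summed weight of placements
    containing it (deamidation probabilities are computed within the given
    placement stratum, which shares one deamidation count).
    """
    if not placements:
        raise ValueError("need at least one placement")
    scores = np.array(
        [_score_placement_fast(spectrum, iso, config) for iso in placements]
    )
    # softmax of 10^(score/10), computed stably
    w = np.power(10.0, (scores - scores.max()) / 10.0)
    probs = w / w.sum()
    xlink: dict[int, float] = {}
    deam: dict[int, float] = {}
    for iso, pr in zip(placements, probs):
        xlink[iso.alpha_q_pos] = xlink.get(iso.alpha_q_pos, 0.0) + pr
        for pos in iso.deamidation:
            deam[pos] = deam.get(pos, 0.0) + pr
    return probs, xlink, deam


def _deamidation_site_sets(sequence: str, q_pos: int, k: int, cap: int):
    """Deterministic enumeration of k-subsets of admissible deamidation sites."""
    from itertools import combinations

    sites = [i + 1 for i, r in enumerate(sequence) if r in "NQ" and i + 1 != q_pos]
    return list(combinations(sites, k))[:cap]


def candidate_placements(
    peptide: "Peptide | str",
    beta,
    beta_k_pos: int,
    n_deamidations: int,
    max_placements: int = 2000,
) -> list[Isopeptide]:
    """All admissible (crosslink Q, deamidation set) placements for one candidate.

    When the combinatorial count exceeds ``max_placements``, truncation is
    applied round-robin across crosslink positions so no candidate site is
    starved.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    q_positions = [i + 1 for i, r in enumerate(seq) if r == "Q"]
    per_q = {
        q: _deamidation_site_sets(seq, q, n_deamidations, max_placements)
        for q in q_positions
    }
    out: list[Isopeptide] = []
    depth = 0
    while len(out) < max_placements:
        emitted = False
        for q in q_positions:
            sets = per_q[q]
            if depth < len(sets):
                out.append(
                    Isopeptide(
                        alpha=peptide, beta=beta,
                        alpha_q_pos=q, beta_k_pos=beta_k_pos,
                        deamidation=sets[depth],
                    )
                )
                emitted = True
                if len(out) >= max_placements:
                    break
        if not emitted:
            break
        depth += 1
    return out


def select_placements(
    spectrum: Spectrum,
    peptide: "Peptide | str",
    beta,
    beta_k_pos: int,
    n_deamidations: int,
    config: SearchConfig,
) -> list[Isopeptide]:
    """Placements to localize over: exhaustive when small, guided when large.

    When the full (crosslink Q × deamidation k-subset) space fits within
    ``max_placements_per_candidate`` it is enumerated exactly.  Otherwise each
    crosslink site gets its deamidation set built by greedy forward selection
    against the spectrum, and the best site's set is additionally surrounded by
    all single-site swaps, so deamidation alternatives remain represented in
    the localization posterior.
    """
    from math import comb

    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    q_positions = [i + 1 for i, r in enumerate(seq) if r == "Q"]
    nq_count = sum(1 for r in seq if r in "NQ")
    total = sum(comb(max(nq_count - 1, 0), n_deamidations) for _ in q_positions)
    if total <= config.max_placements_per_candidate:
        return candidate_placements(
            peptide, beta, beta_k_pos, n_deamidations,
            config.max_placements_per_candidate,
        )

    def make(q, deam):
        return Isopeptide(alpha=peptide, beta=beta, alpha_q_pos=q,
                          beta_k_pos=beta_k_pos, deamidation=tuple(sorted(deam)))

    def fast(iso):
        return _score_placement_fast(spectrum, iso, config)

    best_per_q: list[tuple[float, Isopeptide]] = []
    for q in q_positions:
        sites = [i + 1 for i, r in enumerate(seq) if r in "NQ" and i + 1 != q]
        chosen: tuple[int, ...] = ()
        score = fast(make(q, chosen))
        for _ in range(n_deamidations):
            stage = [
                (fast(make(q, chosen + (s,))), s) for s in sites if s not in chosen
            ]
            if not stage:
                break
            score, site = max(stage, key=lambda t: (t[0], -t[1]))
            chosen = chosen + (site,)
        if len(chosen) == n_deamidations:
            best_per_q.append((score, make(q, chosen)))
    if not best_per_q:
        return []
    placements = {(p.alpha_q_pos, p.deamidation): p for _, p in best_per_q}
    _, best = max(best_per_q, key=lambda t: t[0])
    sites = [i + 1 for i, r in enumerate(seq)
             if r in "NQ" and i + 1 != best.alpha_q_pos]
    for out_site in best.deamidation:  # single-site swap neighborhood
        for in_site in sites:
            if in_site in best.deamidation:
                continue
            deam = tuple(sorted(set(best.deamidation) - {out_site} | {in_site}))
            p = make(best.alpha_q_pos, deam)
            placements.setdefault((p.alpha_q_pos, p.deamidation), p)
    return list(placements.values())


def shuffle_decoy(sequence: str, rng: np.random.Generator) -> str:
    """Shuffled-sequence decoy keeping the C-terminal residue in place."""
    body = list(sequence[:-1])
    rng.shuffle(body)
    return "".join(body) + sequence[-1]


def digest_database(
    proteins: Mapping[str, str],
    config: SearchConfig,
) -> list[Peptide]:
    """Unique candidate peptides from all proteins under the run's digestion settings."""
    seen: dict[str, Peptide] = {}
    for pid in sorted(proteins):
        for pep in digest(
            proteins[pid],
            config.enzymes,
            max_missed=config.max_missed_cleavages,
            specificity=config.specificity,
            protein_id=pid,
            min_length=config.min_peptide_length,
            max_length=config.max_peptide_length,
        ):
            seen.setdefault(pep.sequence, pep)
    return sorted(seen.values(), key=lambda p: p.sequence)


def run_discovery_search(
    spectra: Sequence[Spectrum],
    gluten_proteins: Mapping[str, str],
    tg2_peptide: str,
    config: SearchConfig | None = None,
    include_decoys: bool = False,
) -> list[SpectrumMatch]:
    """Search every spectrum for crosslinked candidates with one active TG2 modification.

    Returns rank-ordered matches (all spectra pooled) that pass the
    modified-peptide score threshold.  With ``include_decoys`` shuffled-sequence
    decoys compete alongside targets and are flagged in the output.
    """
    config = config or SearchConfig()
    if not gluten_proteins:
        raise ValueError("empty gluten protein database")
    if "K" not in tg2_peptide:
        raise ValueError("TG2 peptide must contain the crosslink lysine")
    if not spectra:
        return []

    beta_k_pos = tg2_peptide.index("K") + 1
    xmod_mass = monoisotopic_mass(xlink_modification_composition(tg2_peptide))

    candidates = [p for p in digest_database(gluten_proteins, config) if "Q" in p.sequence]
    rng = np.random.default_rng(config.seed)
    pool: list[tuple[Peptide, bool]] = [(p, False) for p in candidates]
    if include_decoys:
        for p in candidates:
            dseq = shuffle_decoy(p.sequence, rng)
            if "Q" in dseq:
                pool.append((Peptide(sequence=dseq, protein_id=f"decoy_{p.protein_id}"), True))

    masses = np.array([peptide_mass(p.sequence) for p, _ in pool])
    order = np.argsort(masses, kind="stable")
    masses = masses[order]
    pool = [pool[i] for i in order]

    logger.info(
        "discovery search: %d spectra, %d candidate peptides, modification %s (%.4f Da)",
        len(spectra), len(pool), tg2_peptide, xmod_mass,
    )

    results: list[SpectrumMatch] = []
    for spectrum in spectra:
        target = spectrum.neutral_mass
        tol = target * config.precursor_tol_ppm * 1e-6
        scored: list[SpectrumMatch] = []
        for k in range(0, config.max_modifications):  # crosslink + k deamidations
            alpha_mass = target - xmod_mass - k * DEAMIDATION_MASS
            lo = np.searchsorted(masses, alpha_mass - tol, side="left")
            hi = np.searchsorted(masses, alpha_mass + tol, side="right")
            for idx in range(lo, hi):
                peptide, is_decoy = pool[idx]
                placements = select_placements(
                    spectrum, peptide, tg2_peptide, beta_k_pos, k, config
                )
                if not placements:
                    continue
                probs, xlink_probs, deam_probs = localize_sites(
                    spectrum, placements, config
                )
                best_i = int(np.argmax(probs))
                best = placements[best_i]
                score, matched, n_theor = _score_placement(spectrum, best, config)
                scored.append(
                    SpectrumMatch(
                        scan_id=spectrum.scan_id,
                        retention_time=spectrum.retention_time,
                        isopeptide=best,
                        score=score,
                        rank=0,
                        matched_fragments=matched,
                        n_theoretical=n_theor,
                        crosslink_site_probs=xlink_probs,
                        deamidation_site_probs=deam_probs,
                        is_decoy=is_decoy,
                    )
                )
        scored.sort(
            key=lambda m: (-m.score, -len(m.matched_fragments), m.isopeptide.alpha_seq)
        )
        for rank, m in enumerate(scored, start=1):
            m.rank = rank
        results.extend(m for m in scored if m.score >= config.min_score_modified)
    return results
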