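"""Ground-truth simulator for the crosslink-identification pipeline.

Generates proline/glutamine-rich, repetitive gluten-like proteins, forms true
isopeptides between their digestion products and the seven single-lysine TG2
donor peptides, and renders DDA spectra (replicated samples plus negative
controls in which crosslinks are absent) and PRM chromatogram runs — all
traceable to a manifest, so sensitivity/specificity of the full pipeline can
be measured against known truth.

The generator models what the analysis assumes and no more: fragment subsets
are drawn per a coverage fraction, m/z values jitter within the matching
tolerance, intensities are log-normal (only rank/threshold behaviour matters
downstream), retention times are uniform over a gradient window with Gaussian
replicate jitter, and noise peaks are uniform in m/z.  No chromatographic
physics or ionization efficiency is modelled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import isotope_abundances
from .digestion import GASTROINTESTINAL, STUDY_DONOR_PEPTIDES, digest
from .isopeptide import (
    FragmentConfig,
    Isopeptide,
    enumerate_fragments,
    precursor_mass,
    precursor_mz,
)
from .motifs import QXP_FAMILY, classify_glutamine_context
from .search import Spectrum
from .validate import RunDesign

__all__ = [
    "SimulationConfig",
    "TrueIsopeptide",
    "GroundTruthManifest",
    "generate_reference_set",
    "simulate_dda_run",
    "simulate_prm_run",
    "write_fasta",
    "write_mgf",
    "read_mgf_with_envelope",
]

#: Residues used for the non-QPFL bulk of gluten-like sequences (no K/R/C/M:
#: prolamins are lysine-poor, and keeping the filler alphabet small keeps the
#: digest landscape predictable).
_OTHER_RESIDUES = "SEAGVTINHYD"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; identical seeds give identical outputs."""

    seed: int = 0
    n_proteins: int = 6
    protein_length: tuple[int, int] = (300, 500)
    q_freq: float = 0.30
    p_freq: float = 0.20
    f_freq: float = 0.05
    l_freq: float = 0.08
    n_isopeptides: int = 20
    motif_bias: float = 0.7
    deamidation_prob: float = 0.2
    max_deamidations: int = 3
    fragment_coverage: float = 1.0
    n_noise_peaks: int = 0
    noise_mu: float = 4.0  # log-normal parameters of noise peak intensity
    noise_sigma: float = 0.5
    signal_mu: float = 8.0
    signal_sigma: float = 0.8
    n_sample_replicates: int = 3
    n_controls: int = 3
    charges: tuple[int, ...] = (2, 3, 4)
    charge_probs: tuple[float, ...] = (0.45, 0.45, 0.10)
    rt_window: tuple[float, float] = (10.0, 70.0)
    rt_jitter_sd: float = 0.1
    mz_jitter: float = 0.15
    precursor_ppm_jitter: float = 1.0
    n_background_peptides: int = 30
    prm_peak_width: float = 0.08  # Gaussian sigma, minutes
    prm_scan_interval: float = 0.02  # minutes
    fragment_config: FragmentConfig = field(default_factory=FragmentConfig)

    def design(self) -> RunDesign:
        return RunDesign(
            samples=tuple(f"sample_{i+1}" for i in range(self.n_sample_replicates)),
            controls=tuple(f"control_{i+1}" for i in range(self.n_controls)),
        )


@dataclass
class TrueIsopeptide:
    """One injected ground-truth crosslink with its acquisition parameters."""

    id: str
    isopeptide: Isopeptide
    retention_time: float
    charge: int


@dataclass
class GroundTruthManifest:
    """Everything needed to audit a simulated experiment."""

    seed: int
    proteins: dict[str, str]
    isopeptides: list[TrueIsopeptide]
    background_peptides: list[str]
    spectrum_provenance: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "proteins": self.proteins,
            "background_peptides": self.background_peptides,
            "isopeptides": [
                {
                    "id": t.id,
                    "alpha": t.isopeptide.alpha_seq,
                    "beta": t.isopeptide.beta_seq,
                    "alpha_q_pos": t.isopeptide.alpha_q_pos,
                    "beta_k_pos": t.isopeptide.beta_k_pos,
                    "deamidation": list(t.isopeptide.deamidation),
                    "retention_time": t.retention_time,
                    "charge": t.charge,
                }
                for t in self.isopeptides
            ],
            "spectrum_provenance": self.spectrum_provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


class SimulationError(ValueError):
    pass


def _residue_probabilities(config: SimulationConfig) -> tuple[str, np.ndarray]:
    major = {"Q": config.q_freq, "P": config.p_freq, "F": config.f_freq, "L": config.l_freq}
    rest = 1.0 - sum(major.values())
    if rest < 0:
        raise SimulationError("residue frequencies exceed 1")
    alphabet = "".join(major) + _OTHER_RESIDUES
    probs = np.array(list(major.values()) + [rest / len(_OTHER_RESIDUES)] * len(_OTHER_RESIDUES))
    return alphabet, probs


def generate_reference_set(
    config: SimulationConfig,
) -> tuple[dict[str, str], GroundTruthManifest]:
    """Gluten-like proteins plus true isopeptides drawn from their digests."""
    rng = np.random.default_rng(config.seed)
    alphabet, probs = _residue_probabilities(config)
    proteins: dict[str, str] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(config.protein_length[0], config.protein_length[1] + 1))
        seq = "".join(rng.choice(list(alphabet), size=length, p=probs))
        proteins[f"synthetic_prolamin_{i+1}"] = seq

    # candidate alpha peptides: digestible, Q-containing, search-sized
    peptides: dict[str, str] = {}
    for pid in sorted(proteins):
        for pep in digest(proteins[pid], GASTROINTESTINAL, max_missed=2,
                          protein_id=pid, min_length=5, max_length=30):
            if "Q" in pep.sequence:
                peptides.setdefault(pep.sequence, pid)
    alpha_pool = sorted(peptides)
    if len(alpha_pool) < config.n_isopeptides:
        raise SimulationError(
            f"only {len(alpha_pool)} Q-containing peptides available for "
            f"{config.n_isopeptides} requested isopeptides"
        )
    chosen = rng.choice(len(alpha_pool), size=config.n_isopeptides, replace=False)

    truths: list[TrueIsopeptide] = []
    for n, idx in enumerate(sorted(chosen)):
        alpha = alpha_pool[idx]
        beta = STUDY_DONOR_PEPTIDES[n % len(STUDY_DONOR_PEPTIDES)]
        q_positions = [i + 1 for i, r in enumerate(alpha) if r == "Q"]
        preferred = [
            q for q in q_positions
            if classify_glutamine_context(alpha, q) in QXP_FAMILY + ("QXXF*",)
        ]
        if preferred and rng.random() < config.motif_bias:
            q_pos = int(preferred[rng.integers(len(preferred))])
        else:
            q_pos = int(q_positions[rng.integers(len(q_positions))])
        deam_candidates = [
            i + 1 for i, r in enumerate(alpha) if r in "NQ" and i + 1 != q_pos
        ]
        deam = tuple(
            int(p) for p in deam_candidates
            if rng.random() < config.deamidation_prob
        )[: config.max_deamidations]
        iso = Isopeptide(
            alpha=alpha, beta=beta,
            alpha_q_pos=q_pos, beta_k_pos=beta.index("K") + 1,
            deamidation=deam, identifier=f"sim_{n+1:03d}",
        )
        rt = float(rng.uniform(*config.rt_window))
        charge = int(rng.choice(config.charges, p=config.charge_probs))
        truths.append(TrueIsopeptide(f"sim_{n+1:03d}", iso, rt, charge))

    background = sorted(rng.choice(alpha_pool, size=min(config.n_background_peptides,
                                                        len(alpha_pool)), replace=False))
    manifest = GroundTruthManifest(
        seed=config.seed, proteins=proteins, isopeptides=truths,
        background_peptides=[str(b) for b in background],
    )
    return proteins, manifest


def _plain_peptide_spectrum(seq, rt, scan_id, rng, config) -> Spectrum:
    """An MS2 spectrum of an ordinary (non-crosslinked) peptide."""
    from .chem import peptide_composition, peptide_mass

    # b/y ladder of the unmodified peptide
    mzs, ints = [], []
    from .chem import mz_from_mass, monoisotopic_mass, residue_composition, WATER
    prefix = 0.0
    masses = [monoisotopic_mass(residue_composition(r)) for r in seq]
    water = monoisotopic_mass(WATER)
    total = sum(masses) + water
    acc = 0.0
    for i in range(len(seq) - 1):
        acc += masses[i]
        for frag_mass in (acc, total - acc):  # b_i, y_(n-i)
            mzs.append(mz_from_mass(frag_mass, 1) + rng.uniform(-config.mz_jitter, config.mz_jitter))
            ints.append(float(rng.lognormal(config.signal_mu, config.signal_sigma)))
    _add_noise(mzs, ints, rng, config)
    charge = 2
    pre_mz = mz_from_mass(total, charge)
    pre_mz *= 1 + rng.uniform(-1, 1) * config.precursor_ppm_jitter * 1e-6
    env = isotope_abundances(peptide_composition(seq), 4)
    env = env * (1 + rng.normal(0, 0.005, size=env.size)).clip(min=0)
    return Spectrum(
        scan_id=scan_id, precursor_mz=pre_mz, precursor_charge=charge,
        retention_time=rt, mz=np.array(mzs), intensity=np.array(ints),
    ), env


def _add_noise(mzs, ints, rng, config):
    for _ in range(config.n_noise_peaks):
        mzs.append(float(rng.uniform(150.0, 1700.0)))
        ints.append(float(rng.lognormal(config.noise_mu, config.noise_sigma)))


def simulate_dda_run(
    manifest: GroundTruthManifest,
    config: SimulationConfig,
) -> dict[str, list[Spectrum]]:
    """MS2 spectra per run: true isopeptides in every sample replicate, never in controls.

    Every run also contains spectra of ordinary background peptides.  Each
    spectrum records the expected precursor isotope envelope (with small
    multiplicative noise) alongside the peak list, emulating the precursor
    full-scan information used for the isotope dot product.
    """
    from .isopeptide import composition as iso_composition

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    design = config.design()
    runs: dict[str, list[Spectrum]] = {}
    scan_counter = 0

    for run_id in design.samples + design.controls:
        spectra: list[Spectrum] = []
        is_sample = run_id in design.samples
        if is_sample:
            for truth in manifest.isopeptides:
                scan_counter += 1
                scan_id = f"{run_id}.scan{scan_counter}"
                frags = enumerate_fragments(truth.isopeptide, config.fragment_config)
                n_keep = int(round(config.fragment_coverage * len(frags)))
                keep = sorted(rng.choice(len(frags), size=n_keep, replace=False)) \
                    if n_keep < len(frags) else range(len(frags))
                mzs = [
                    frags[i].mz + rng.uniform(-config.mz_jitter, config.mz_jitter)
                    for i in keep
                ]
                ints = [float(rng.lognormal(config.signal_mu, config.signal_sigma))
                        for _ in keep]
                _add_noise(mzs, ints, rng, config)
                pre_mz = precursor_mz(truth.isopeptide, truth.charge)
                pre_mz *= 1 + rng.uniform(-1, 1) * config.precursor_ppm_jitter * 1e-6
                env = isotope_abundances(iso_composition(truth.isopeptide), 4)
                env = env * (1 + rng.normal(0, 0.005, size=env.size)).clip(min=0)
                spec = Spectrum(
                    scan_id=scan_id, precursor_mz=pre_mz,
                    precursor_charge=truth.charge,
                    retention_time=truth.retention_time + rng.normal(0, config.rt_jitter_sd),
                    mz=np.array(mzs), intensity=np.array(ints),
                )
                spec.precursor_envelope = env
                spectra.append(spec)
                manifest.spectrum_provenance[scan_id] = truth.id
        for seq in manifest.background_peptides:
            scan_counter += 1
            scan_id = f"{run_id}.scan{scan_counter}"
            rt = float(rng.uniform(*config.rt_window))
            spec, env = _plain_peptide_spectrum(seq, rt, scan_id, rng, config)
            spec.precursor_envelope = env
            spectra.append(spec)
            manifest.spectrum_provenance[scan_id] = f"peptide:{seq}"
        runs[run_id] = spectra
    return runs


def simulate_prm_run(
    targets: Sequence,
    manifest: GroundTruthManifest,
    config: SimulationConfig,
    drop_transitions: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, list[Spectrum]]:
    """Unscheduled PRM runs with Gaussian elution of every (kept) transition.

    ``targets`` come from the targeted-method builder; a target is only
    injected when its isopeptide id appears in the manifest.  In negative
    controls no isopeptide signal is injected.  ``drop_transitions`` maps
    target name → transition labels withheld (e.g. site-determining ions of a
    rejected site).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    design = config.design()
    truth_by_id = {t.id: t for t in manifest.isopeptides}
    drop = {k: set(v) for k, v in (drop_transitions or {}).items()}
    # one acquisition series per (isopeptide, charge): the two representations
    # describe the same molecule, so their transitions co-occur in its scans
    series: dict[tuple[str, int], list] = {}
    for target in targets:
        if target.isopeptide_id in truth_by_id:
            series.setdefault((target.isopeptide_id, target.charge), []).append(target)
    runs: dict[str, list[Spectrum]] = {}
    for run_id in design.samples + design.controls:
        is_sample = run_id in design.samples
        spectra: list[Spectrum] = []
        for (iso_id, charge), group in series.items():
            truth = truth_by_id[iso_id]
            rt0 = truth.retention_time + (rng.normal(0, config.rt_jitter_sd) if is_sample else 0.0)
            times = np.arange(rt0 - 0.6, rt0 + 0.6, config.prm_scan_interval)
            transitions = []  # (label, mz, amplitude), deduplicated across representations
            seen = set()
            for target in group:
                dropped = drop.get(target.name, set())
                for trans in target.transitions:
                    if trans.label in dropped or trans.label in seen:
                        continue
                    seen.add(trans.label)
                    transitions.append(
                        (trans.mz, float(rng.lognormal(config.signal_mu, config.signal_sigma)))
                    )
            precursor_mz = group[0].precursor_mz
            for k, t in enumerate(times):
                mzs, ints = [], []
                if is_sample:
                    g = np.exp(-0.5 * ((t - rt0) / config.prm_peak_width) ** 2)
                    for mz, amplitude in transitions:
                        height = amplitude * g
                        if height > 1.0:
                            mzs.append(mz)
                            ints.append(height)
                spectra.append(
                    Spectrum(
                        scan_id=f"{run_id}.{iso_id}.z{charge}.{k}",
                        precursor_mz=precursor_mz,
                        precursor_charge=charge,
                        retention_time=float(t),
                        mz=np.array(mzs), intensity=np.array(ints),
                        isolation_width=1.7,
                    )
                )
        runs[run_id] = spectra
    return runs


# --- plain-text writers ------------------------------------------------------


def write_fasta(proteins: Mapping[str, str], path) -> None:
    import textwrap

    with open(path, "w") as fh:
        for pid in proteins:
            fh.write(f">{pid}\n")
            fh.write("\n".join(textwrap.wrap(proteins[pid], 60)) + "\n")


def write_mgf(spectra: Sequence[Spectrum], path, seed: int | None = None) -> None:
    """Write spectra as MGF; the precursor envelope travels in a custom header."""
    from pyteomics import mgf as _mgf

    entries = []
    for s in spectra:
        params = {
            "title": s.scan_id,
            "pepmass": s.precursor_mz,
            "charge": f"{s.precursor_charge}+",
            "rtinseconds": s.retention_time * 60.0,
        }
        env = getattr(s, "precursor_envelope", None)
        if env is not None:
            params["isoenvelope"] = ",".join(f"{x:.6g}" for x in env)
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    header = f"# seed={seed}" if seed is not None else ""
    _mgf.write(entries, output=str(path), header=header, file_mode="w")


def read_mgf_with_envelope(path) -> list[Spectrum]:
    """Read MGF written by :func:`write_mgf`, restoring precursor envelopes."""
    from .search import _read_mgf
    from pyteomics import mgf as _mgf

    spectra = _read_mgf(str(path))
    with _mgf.MGF(str(path)) as reader:
        for spec, raw in zip(spectra, reader):
            env = raw["params"].get("isoenvelope")
            if env:
                spec.precursor_envelope = np.array([float(x) for x in str(env).split(",")])
    return spectra
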