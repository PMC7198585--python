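"""Targeted validation: isolation lists, chromatograms, PRM verdicts."""

import numpy as np
import pytest

from isoxlink.chem import PROTON_MASS
from isoxlink.isopeptide import FragmentConfig, Isopeptide, precursor_mass
from isoxlink.prm import (
    Chromatogram,
    PrmTarget,
    build_isolation_list,
    extract_chromatograms,
    isolation_list_table,
    prm_confirm,
    read_isolation_list,
    write_isolation_list,
)
from isoxlink.search import Spectrum
from isoxlink.validate import ConfirmationThresholds, DesignError, RunDesign

DESIGN = RunDesign(samples=("s1",), controls=("c1",))


@pytest.fixture()
def iso():
    return Isopeptide("AQIPQQL", "FLKNAGR", alpha_q_pos=2, beta_k_pos=3)


def test_isolation_list_combinatorics(iso):
    targets = build_isolation_list({"X1": iso}, charges=(2, 3))
    assert len(targets) == 4  # 2 charges x 2 representations
    by_charge = {}
    for t in targets:
        by_charge.setdefault(t.charge, set()).add(round(t.precursor_mz, 6))
    # alpha-base and beta-base rows describe the same molecule
    assert all(len(v) == 1 for v in by_charge.values())
    m = precursor_mass(iso)
    for t in targets:
        assert t.precursor_mz == pytest.approx((m + t.charge * PROTON_MASS) / t.charge, abs=1e-4)


def test_isolation_list_round_trip(iso, tmp_path):
    targets = build_isolation_list({"X1": iso}, charges=(2, 3))
    path = tmp_path / "list.tsv"
    write_isolation_list(targets, path)
    df = read_isolation_list(path)
    assert set(df["name"]) == {t.name for t in targets}
    assert np.allclose(df["end"] - df["start"], 1.7)
    with pytest.raises(ValueError):
        build_isolation_list({})


def _gaussian_run(target, rt0=30.0, width=0.08, dt=0.02, amplitude=1e6, drop=()):
    times = np.arange(rt0 - 0.5, rt0 + 0.5, dt)
    spectra = []
    for k, t in enumerate(times):
        g = np.exp(-0.5 * ((t - rt0) / width) ** 2)
        mzs, ints = [], []
        for trans in target.transitions:
            if trans.label in drop:
                continue
            h = amplitude * g
            if h > 1.0:
                mzs.append(trans.mz)
                ints.append(h)
        spectra.append(
            Spectrum(f"scan{k}", target.precursor_mz, target.charge, float(t),
                     np.array(mzs), np.array(ints), isolation_width=1.7)
        )
    return spectra


def test_extract_chromatograms_coelution_and_area(iso):
    [target] = build_isolation_list(
        {"X1": iso}, charges=(2,), fragment_config=FragmentConfig(
            ion_types=("b", "y"), include_a=False, losses=(), max_charge=1)
    )[:1]
    spectra = _gaussian_run(target)
    chroms = extract_chromatograms(spectra, [target], fragment_tol=0.5)[target.name]
    detected = [c for c in chroms if c.detected]
    assert len(detected) == len(target.transitions)
    apexes = [c.peak_apex for c in detected]
    assert max(apexes) - min(apexes) <= 0.02  # within one scan interval
    # recovered area vs the analytically injected one (zero noise)
    c0 = detected[0]
    times = c0.times
    g = 1e6 * np.exp(-0.5 * ((times - 30.0) / 0.08) ** 2)
    injected = np.trapezoid(np.where(g > 1.0, g, 0.0), times)
    assert c0.area == pytest.approx(injected, rel=0.05)


def test_absent_target_gives_empty_traces(iso):
    [target] = build_isolation_list({"X1": iso}, charges=(2,))[:1]
    far = Spectrum("s", target.precursor_mz + 50.0, 2, 30.0,
                   np.array([300.0]), np.array([1.0]))
    chroms = extract_chromatograms([far], [target])[target.name]
    assert all(len(c.times) == 0 and not c.detected for c in chroms)


def _confirm(target, sample_spectra, control_spectra, **kw):
    chroms = {
        "s1": extract_chromatograms(sample_spectra, [target])[target.name],
        "c1": extract_chromatograms(control_spectra, [target])[target.name],
    }
    return prm_confirm(chroms, DESIGN, isopeptide_id="X1", **kw)


def _empty_run(target, rt0=30.0, dt=0.02):
    times = np.arange(rt0 - 0.5, rt0 + 0.5, dt)
    return [
        Spectrum(f"c{k}", target.precursor_mz, target.charge, float(t),
                 np.array([]), np.array([]), isolation_width=1.7)
        for k, t in enumerate(times)
    ]


def _simple_target(iso):
    [t] = build_isolation_list(
        {"X1": iso}, charges=(2,), fragment_config=FragmentConfig(
            ion_types=("b", "y"), include_a=False, losses=(), max_charge=1)
    )[:1]
    return t


def test_prm_confirm_full_signal(iso):
    target = _simple_target(iso)
    verdict = _confirm(target, _gaussian_run(target), _empty_run(target))
    assert verdict.verdict == "confirmed"
    assert verdict.n_coeluting_by >= 7
    assert verdict.max_consecutive >= 3


def test_prm_confirm_needs_seven_transitions(iso):
    target = _simple_target(iso)
    # keep only six b/y transitions
    keep = {t.label for t in target.transitions[:6]}
    drop = {t.label for t in target.transitions} - keep
    verdict = _confirm(target, _gaussian_run(target, drop=drop), _empty_run(target))
    assert verdict.verdict == "rejected"
    assert "min-fragments" in verdict.reasons


def test_prm_confirm_rejects_control_signal(iso):
    target = _simple_target(iso)
    verdict = _confirm(target, _gaussian_run(target), _gaussian_run(target))
    assert verdict.verdict == "rejected"
    assert "negative-control" in verdict.reasons


def test_prm_confirm_monotone_in_transition_count(iso):
    target = _simple_target(iso)
    labels = [t.label for t in target.transitions]
    order = {"rejected": 0, "confirmed": 1}
    last = 0
    for n_keep in (4, 7, len(labels)):
        drop = set(labels[n_keep:])
        verdict = _confirm(target, _gaussian_run(target, drop=drop), _empty_run(target))
        assert order[verdict.verdict] >= last or verdict.verdict == "rejected"
        if verdict.verdict == "confirmed":
            last = 1
    assert last == 1


def test_prm_site_assignment_exhaustive(iso):
    """Site-determining transitions present for one site always assign that site."""
    target = _simple_target(iso)
    labels = [t.label for t in target.transitions]
    site_map = {2: labels[:3], 5: labels[3:6]}
    for true_site, other in ((2, 5), (5, 2)):
        drop = set(site_map[other])
        chroms = {
            "s1": extract_chromatograms(_gaussian_run(target, drop=drop), [target])[target.name],
            "c1": extract_chromatograms(_empty_run(target), [target])[target.name],
        }
        verdict = prm_confirm(chroms, DESIGN, site_determining=site_map, isopeptide_id="X1")
        assert verdict.assigned_site == true_site


def test_prm_requires_control_data(iso):
    target = _simple_target(iso)
    with pytest.raises(DesignError):
        prm_confirm({"s1": []}, DESIGN)


def test_rt_consistency_with_discovery(iso):
    target = _simple_target(iso)
    verdict = _confirm(
        target, _gaussian_run(target, rt0=30.0), _empty_run(target), expected_rt=35.0
    )
    assert "retention-time-vs-discovery" in verdict.reasons
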