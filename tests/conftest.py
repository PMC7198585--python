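import pytest

from isoxlink.fixtures import load_paper_isopeptides, load_tg2_sequence
from isoxlink.isopeptide import Isopeptide


@pytest.fixture(scope="session")
def paper_records():
    return load_paper_isopeptides()


@pytest.fixture(scope="session")
def tg2_sequence():
    return load_tg2_sequence()


@pytest.fixture(scope="session")
def fixture_isopeptides(paper_records):
    """Isopeptide objects for every record with an unambiguous crosslink site."""
    out = {}
    for rec in paper_records:
        if rec.crosslink_q is None:
            continue
        out[rec.id] = Isopeptide(
            alpha=rec.gluten_peptide,
            beta=rec.tg2_peptide,
            alpha_q_pos=rec.crosslink_q,
            beta_k_pos=rec.beta_k_pos,
            deamidation=rec.deamidation,
            identifier=rec.id,
        )
    return out


@pytest.fixture()
def w3_isopeptide():
    """The well-characterised γ-gliadin × FLKNAGR example (crosslink Q10, deamidation Q4)."""
    return Isopeptide(
        alpha="VQGQGIIQPQQPAQL", beta="FLKNAGR",
        alpha_q_pos=10, beta_k_pos=3, deamidation=(4,), identifier="W3",
    )
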