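import pytest

from lymprofiler.reference import GeneSegment, ReferenceDatabase
from lymprofiler.simulate import generate_synthetic_reference


def make_gene(gene_id, seq, segment_class=None, chain="TRB"):
    cls = segment_class or gene_id.lstrip(chain)[0]
    return GeneSegment(
        gene_id=gene_id, segment_class=cls, chain=chain, sequence=seq
    )


@pytest.fixture(scope="session")
def tiny_db():
    """Hand-built 2V/1D/2J database with known CDR3 anchors."""
    db = ReferenceDatabase(chain="TRB")
    #                     tags occupy the last 25 nt; Cys codon at index 30
    v1 = "ACGGTAGCTAGCTAACCGGTTACGATCGAT" + "TGTGCC" + "AGTCACGATACGGATTACCAGGG"
    v2 = v1[:5] + "T" + v1[6:40] + "C" + v1[41:]  # differs at positions 5 and 40
    db.add(make_gene("TRBV1*01", v1))
    db.add(make_gene("TRBV2*01", v2))
    db.add(make_gene("TRBD1*01", "GGGACAGGGGGC"))
    # J genes: 15-nt unique prefixes; [FW]GXG motif (TTTGGAACGGGT = F G T G)
    j1 = "GAACTCAACGTCTGA" + "ACCCGA" + "TTTGGAACGGGT" + "ACCAAACTCGAAG"
    j2 = "CATTCGATTGCCAAT" + "GTGCAC" + "TTCGGCGCAGGC" + "TCTAGACTTATCG"
    db.add(make_gene("TRBJ1*01", j1))
    db.add(make_gene("TRBJ2*01", j2))
    db.validate()
    db.annotate()
    return db


@pytest.fixture(scope="session")
def synth_db():
    """Small simulator-generated TCR database (10V x 2 alleles, 2D, 5J)."""
    return generate_synthetic_reference(10, 2, 5, seed=101)


@pytest.fixture(scope="session")
def synth_db_ig():
    """IG-light-style database: V and J only, no D pool."""
    return generate_synthetic_reference(8, 0, 4, seed=202, chain="IGL")
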