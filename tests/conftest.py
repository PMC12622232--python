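import pytest

from pocpu.alignment import AlignmentHit, HitTable
from pocpu.proteome_io import ProteinRecord, Proteome


def make_hit(query_id, subject_id, identity=60.0, aln_length=90, evalue=1e-10):
    """A hit that passes the default conservation filter for ~100-residue queries."""
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=identity,
        aln_length=aln_length,
        evalue=evalue,
        bitscore=100.0,
    )


def make_proteome(genome_id, protein_ids, length=100):
    records = tuple(
        ProteinRecord(pid, "M" + "A" * (length - 1)) for pid in protein_ids
    )
    return Proteome(genome_id=genome_id, records=records)


@pytest.fixture
def worked_example():
    """The duplicated-gene scenario: 4+4 proteins, 3 passing hits each way.

    p1 matches two paralogous subjects (s1, s2), so the a->b direction has 3
    hit rows but only 2 distinct queries; the b->a direction has 3 rows from
    3 distinct queries. POCP = (3+3)/8 x 100 = 75 while
    POCPu = (2+3)/8 x 100 = 62.5.
    """
    proteome_a = make_proteome("gA", ["p1", "p2", "p3", "p4"])
    proteome_b = make_proteome("gB", ["s1", "s2", "s3", "s4"])
    hits_ab = HitTable("gA", "gB", (
        make_hit("p1", "s1"), make_hit("p1", "s2"), make_hit("p2", "s3"),
    ))
    hits_ba = HitTable("gB", "gA", (
        make_hit("s1", "p1"), make_hit("s2", "p1"), make_hit("s3", "p2"),
    ))
    return proteome_a, proteome_b, hits_ab, hits_ba
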