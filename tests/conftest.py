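import numpy as np
import pysam
import pytest

from mtcnkit.lpwgs import classify_contigs
from mtcnkit.qpcr import CtMeasurement


def make_segment(header, ref_id, start, cigar, mapq=60, flag=0, name="r"):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_id = ref_id
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigartuples = cigar
    return a


def toy_header(contigs):
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": length} for n, length in contigs],
    })


SMALL_CONTIGS = (("chr1", 5000), ("chr2", 4000), ("chrX", 3000), ("chrM", 1000))


def random_alignment_fixture(seed, n_reads=200):
    """Messy toy alignments: mixed CIGARs, MAPQs, duplicate/secondary flags."""
    rng = np.random.default_rng(seed)
    header = toy_header(SMALL_CONTIGS)
    reads = []
    for i in range(n_reads):
        ref_id = int(rng.integers(0, len(SMALL_CONTIGS)))
        length = SMALL_CONTIGS[ref_id][1]
        kind = rng.integers(0, 4)
        if kind == 0:
            cigar = [(0, 100)]
        elif kind == 1:
            cigar = [(4, 20), (0, 60), (4, 20)]
        elif kind == 2:
            cigar = [(0, 40), (2, 5), (0, 55)]  # deletion consumes reference
        else:
            cigar = [(0, 50), (1, 10), (0, 40)]  # insertion does not
        span = sum(n for op, n in cigar if op in (0, 2, 3, 7, 8))
        start = int(rng.integers(0, length - span + 1))
        mapq = int(rng.choice([0, 30, 60]))
        flag = 0
        if rng.random() < 0.1:
            flag |= 0x400  # duplicate
        if rng.random() < 0.1:
            flag |= 0x100  # secondary
        reads.append(make_segment(header, ref_id, start, cigar, mapq, flag, name=f"r{i}"))
    return classify_contigs(SMALL_CONTIGS), reads


@pytest.fixture
def small_classification():
    return classify_contigs(SMALL_CONTIGS)


def triplicate(sample_id, gene, cts, **kwargs):
    return [CtMeasurement(sample_id, gene, i + 1, ct, **kwargs)
            for i, ct in enumerate(cts)]


def four_gene_plate(sample_id, nd1, nd6, becn1, neb):
    """One sample's plate with constant triplicates per gene."""
    wells = []
    for gene, ct in (("ND1", nd1), ("ND6", nd6), ("BECN1", becn1), ("NEB", neb)):
        wells += triplicate(sample_id, gene, [ct] * 3)
    return wells
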