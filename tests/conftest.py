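"""Shared fixtures: small synthetic references and hand-built SAM records."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from l1recall import sim

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1_000_000}]}
)


@pytest.fixture(scope="session")
def consensus():
    return sim.random_consensus(length=3000, seed=11)


@pytest.fixture(scope="session")
def reference(consensus):
    genome, sources = sim.build_reference(150_000, 2, consensus, seed=7)
    return genome, sources


def make_record(
    name="r1",
    chrom="chr1",
    pos=1000,
    seq=None,
    cigar=None,
    read_len=100,
    mapq=60,
    is_read1=True,
    is_reverse=False,
    mate_pos=1400,
    mate_reverse=True,
    mate_chrom="chr1",
    proper=True,
    duplicate=False,
    paired=True,
    supplementary=False,
    unmapped=False,
    mate_unmapped=False,
    tlen=500,
    qual_len=None,
):
    """Build one pysam record with sensible defaults for unit tests."""
    a = pysam.AlignedSegment(HEADER)
    a.query_name = name
    rng = np.random.default_rng(abs(hash(name)) % (2**31))
    if seq is None:
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, read_len))
    a.query_sequence = seq
    n_qual = len(seq) if qual_len is None else qual_len
    a.query_qualities = pysam.qualitystring_to_array("?" * n_qual)
    a.is_paired = paired
    a.is_read1 = is_read1
    a.is_read2 = paired and not is_read1
    a.is_duplicate = duplicate
    a.is_supplementary = supplementary
    if unmapped:
        a.is_unmapped = True
        a.mapping_quality = 0
    else:
        a.reference_name = chrom
        a.reference_start = pos
        a.mapping_quality = mapq
        a.cigartuples = cigar or [(0, len(seq))]
        a.is_reverse = is_reverse
        a.is_proper_pair = proper
    if mate_unmapped:
        a.mate_is_unmapped = True
    elif paired:
        a.next_reference_name = mate_chrom
        a.next_reference_start = mate_pos
        a.mate_is_reverse = mate_reverse
    a.template_length = tlen
    return a


@pytest.fixture()
def make_rec():
    return make_record
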