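import numpy as np
import pytest

from vntrspan.catalog import GenomicInterval, VntrLocus
from vntrspan.coverage import AlignedRead
from vntrspan.simulate import RefSeq


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_reference(contigs):
    """Dict of contig -> sequence wrapped in a fetchable object."""
    return RefSeq(contigs)


def make_locus(chrom="chr1", start=1000, motif="ACGTGG", copies=10, locus_id=None):
    end = start + len(motif) * copies
    return VntrLocus(
        locus_id=locus_id or f"{chrom}:{start}-{end}",
        interval=GenomicInterval(chrom, start, end),
        motif=motif,
    )


def make_spanning_read(
    ref: RefSeq,
    locus: VntrLocus,
    f_left: int = 20,
    f_right: int = 20,
    repeat_count: int = None,
    sample_id: str = "S1",
    read_id: str = "r1",
    mutate_at: tuple = (),
):
    """Build a read spanning ``locus`` with given flanks and repeat count.

    Mirrors a true alignment: flank bases copied from the reference, the
    array replaced by ``repeat_count`` motif copies (indel vs the reference
    array placed at the 3' end).  ``mutate_at`` lists read positions to
    substitute (cyclic A->C->G->T->A).
    """
    iv = locus.interval
    ref_len = iv.end - iv.start
    rc = repeat_count if repeat_count is not None else round(locus.ref_repeat_count)
    array = locus.motif * rc
    left = ref.fetch(iv.chrom, iv.start - f_left, iv.start)
    right = ref.fetch(iv.chrom, iv.end, iv.end + f_right)
    seq = left + array + right
    if len(array) == ref_len:
        cigar = [(0, len(seq))]
    elif len(array) > ref_len:
        cigar = [(0, f_left + ref_len), (1, len(array) - ref_len), (0, f_right)]
    else:
        cigar = [(0, f_left + len(array)), (2, ref_len - len(array)), (0, f_right)]
    if mutate_at:
        cycle = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}
        chars = list(seq)
        for pos in mutate_at:
            chars[pos] = cycle[chars[pos]]
        seq = "".join(chars)
    return AlignedRead(
        read_id=read_id,
        sample_id=sample_id,
        interval=GenomicInterval(iv.chrom, iv.start - f_left, iv.end + f_right),
        sequence=seq,
        cigartuples=cigar,
    )


@pytest.fixture
def simple_reference():
    """600 bp contig with a planted 6x10 'ACGTGG' array at [200, 260)."""
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    left = "".join(bases[rng.integers(0, 4, 200)])
    right = "".join(bases[rng.integers(0, 4, 340)])
    seq = left + "ACGTGG" * 10 + right
    return make_reference({"chr1": seq})


@pytest.fixture
def simple_locus():
    return make_locus("chr1", 200, "ACGTGG", 10)
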