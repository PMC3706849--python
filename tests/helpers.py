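"""Shared builders for hand-constructed reads and pileup columns."""

import numpy as np

from concordx import AlignedRead


def mk_read(chrom, start, seq, run="r", strand="+", mapq=60, qual=30, dup=False):
    return AlignedRead(
        run_id=run,
        chrom=chrom,
        start=start,
        strand=strand,
        mapq=mapq,
        sequence=seq,
        base_qualities=np.full(len(seq), qual, dtype=np.uint8),
        duplicate_flag=dup,
    )


def truth_keys(truth, locus_class):
    """(chrom, pos, ref, alt) keys of planted variants of one class."""
    sub = truth[truth.locus_class == locus_class]
    return set(zip(sub.chrom, sub.pos, sub.ref, sub.alt))
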