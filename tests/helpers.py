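import numpy as np

from lriscape.genomic_io import GenomicInterval, Interaction, RestrictionFragment


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def frag(chrom, start, end, fid=None):
    fid = fid or f"{chrom}:{start}-{end}"
    return RestrictionFragment(GenomicInterval(chrom, start, end), fid)


def make_interaction(chrom="chr1", bait_start=0, bait_end=4000,
                     oe_start=100_000, oe_end=104_000, oe_chrom=None,
                     read_count=5, score=6.0, **kw):
    return Interaction(
        frag(chrom, bait_start, bait_end),
        frag(oe_chrom or chrom, oe_start, oe_end),
        read_count=read_count, score=score, **kw,
    )
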