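import math
from math import comb

import pytest

from fisherseq.annotation import GeneModel, GenomicInterval, Transcript


def make_transcript(tid, gid, exons, chrom="chr1", strand="+"):
    return Transcript(
        transcript_id=tid,
        gene_id=gid,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
    )


def make_gene(gid, transcript_exons, chrom="chr1", strand="+"):
    return GeneModel(
        gene_id=gid,
        transcripts=[
            make_transcript(f"{gid}.t{i}", gid, exons, chrom, strand)
            for i, exons in enumerate(transcript_exons)
        ],
    )


def fisher_enum(a, b, c, d):
    """Independent oracle: exhaustive minimum-likelihood two-sided Fisher P
    over all 2x2 tables with the observed margins."""
    r1, c1, M = a + b, a + c, a + b + c + d
    denom = comb(M, r1)

    def prob(k):
        return comb(c1, k) * comb(M - c1, r1 - k) / denom

    lo, hi = max(0, r1 - (M - c1)), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-12))


def hypergeom_tail_enum(k, N, K, n):
    """Independent oracle: P(overlap >= k) by direct summation."""
    denom = comb(N, n)
    hi = min(K, n)
    return sum(comb(K, j) * comb(N - K, n - j) / denom for j in range(k, hi + 1))


def constitutive_bases_oracle(gene):
    """Per-base set intersection across transcript exonic base sets."""
    base_sets = [
        {(e.chrom, pos) for e in tx.exons for pos in range(e.start, e.end)}
        for tx in gene.transcripts
    ]
    out = base_sets[0]
    for s in base_sets[1:]:
        out &= s
    return out


@pytest.fixture
def two_transcript_gene():
    """Gene with cassette exon B: {A, B, C} and {A, C}."""
    return make_gene("ENSG1", [[(100, 200), (300, 400), (500, 600)],
                               [(100, 200), (500, 600)]])


def assert_close(x, y, rel=1e-9):
    assert math.isclose(x, y, rel_tol=rel, abs_tol=1e-300), (x, y)
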