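"""RPKM quantification and replicate-free pairwise differential expression.

Expression is quantified as RPKM — reads per kilobase of exon model per
million uniquely mapped reads — where the "exon model" is the gene's
constitutive exons.  Differential expression between two libraries (no
replicates) uses a two-sided Fisher's exact test on the 2x2 table

    [[count_a, total_a - count_a],
     [count_b, total_b - count_b]]

which treats each library as a draw of reads and asks whether the gene's
read proportion differs.  Under pure counting (Poisson) noise this test is
conservative.  Raw P-values are Bonferroni-corrected over the number of
genes actually tested in the comparison; significance is adjusted P < alpha
(default 0.05).  M/A values use log2: M = log2(rpkm_a) - log2(rpkm_b),
A = their mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .annotation import GeneModel
from .counting import SampleCounts
from .errors import DataError
from .stats import bonferroni, fisher_two_sided

__all__ = [
    "DEResult",
    "rpkm",
    "de_test",
    "differential_expression",
    "ma_values",
    "de_results_frame",
    "FOLD_CHANGE_REPORT_THRESHOLD_LOG2",
]

# log2 fold-change threshold used to nominate genes for targeted validation
# (fold change > 2**0.4 ~ 1.32)
FOLD_CHANGE_REPORT_THRESHOLD_LOG2 = 0.4


@dataclass
class DEResult:
    gene_id: str
    rpkm_a: float
    rpkm_b: float
    M: float  # log2(rpkm_a / rpkm_b); NaN when either RPKM is 0
    A: float  # 0.5 * (log2 rpkm_a + log2 rpkm_b); NaN when either RPKM is 0
    p_raw: float
    p_adj: float
    significant: bool
    direction: str  # "up" iff rpkm_a > rpkm_b else "down"
    zero_in_both: bool = False  # zero counts in both samples (tested, flagged)


def rpkm(count: int, constitutive_length_bp: int, total_uniquely_mapped: int) -> float:
    """Reads per kilobase of exon model per million uniquely mapped reads.

    Returns NaN (the undefined-RPKM marker) when the exon-model length is
    zero; such genes are excluded from differential testing.
    """
    if count < 0:
        raise DataError("count must be >= 0")
    if total_uniquely_mapped <= 0:
        raise DataError("total_uniquely_mapped must be > 0")
    if constitutive_length_bp <= 0:
        return math.nan
    return count / ((constitutive_length_bp / 1e3) * (total_uniquely_mapped / 1e6))


def de_test(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Two-sided Fisher's exact P for one gene between two libraries."""
    if count_a < 0 or count_b < 0:
        raise DataError("counts must be >= 0")
    if total_a < count_a or total_b < count_b:
        raise DataError("library total smaller than gene count")
    return fisher_two_sided(
        [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    )


def ma_values(rpkm_condition: float, rpkm_reference: float) -> tuple[float, float]:
    """(M, A) in log2; inputs must be positive."""
    if not (rpkm_condition > 0 and rpkm_reference > 0):
        raise DataError("MA values require positive RPKM in both samples")
    m = math.log2(rpkm_condition) - math.log2(rpkm_reference)
    a = 0.5 * (math.log2(rpkm_condition) + math.log2(rpkm_reference))
    return m, a


def _lengths(genes) -> Mapping[str, int]:
    if isinstance(genes, Mapping) and genes and not isinstance(
        next(iter(genes.values())), GeneModel
    ):
        return genes  # already gene_id -> length
    models: Iterable[GeneModel] = (
        genes.values() if isinstance(genes, Mapping) else genes
    )
    out = {}
    for g in models:
        if g.constitutive_length_bp is None:
            raise DataError(f"gene {g.gene_id}: constitutive length not derived")
        out[g.gene_id] = g.constitutive_length_bp
    return out


def differential_expression(
    a: SampleCounts,
    b: SampleCounts,
    genes: Mapping[str, int] | Mapping[str, GeneModel] | Iterable[GeneModel],
    alpha: float = 0.05,
) -> list[DEResult]:
    """Replicate-free pairwise differential expression of sample a vs b.

    ``genes`` supplies exon-model lengths (GeneModels or a gene_id->length
    mapping) and defines the identifier universe: genes absent from it, or
    with zero exon-model length (no computable RPKM), are excluded before
    testing.  Bonferroni m is the number of genes actually tested in this
    comparison.  Genes with zero counts in both samples are tested (P = 1)
    but flagged ``zero_in_both``.  Results are sorted by raw P then gene id.
    """
    lengths = _lengths(genes)
    tested: list[str] = [
        gid
        for gid in sorted(set(a.gene_counts) & set(b.gene_counts))
        if gid and lengths.get(gid, 0) > 0
    ]
    if not tested:
        raise DataError("no genes eligible for differential testing")
    m = len(tested)
    out: list[DEResult] = []
    for gid in tested:
        ca, cb = a.gene_counts[gid], b.gene_counts[gid]
        ra = rpkm(ca, lengths[gid], a.total_uniquely_mapped)
        rb = rpkm(cb, lengths[gid], b.total_uniquely_mapped)
        p = de_test(ca, a.total_uniquely_mapped, cb, b.total_uniquely_mapped)
        padj = bonferroni(p, m)
        if ra > 0 and rb > 0:
            mv, av = ma_values(ra, rb)
        else:
            mv, av = math.nan, math.nan
        out.append(
            DEResult(
                gene_id=gid,
                rpkm_a=ra,
                rpkm_b=rb,
                M=mv,
                A=av,
                p_raw=p,
                p_adj=padj,
                significant=padj < alpha,
                direction="up" if ra > rb else "down",
                zero_in_both=(ca == 0 and cb == 0),
            )
        )
    out.sort(key=lambda r: (r.p_raw, r.gene_id))
    return out


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    """Tidy results table (one row per tested gene); log base 2 for M/A."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "rpkm_a": r.rpkm_a,
                "rpkm_b": r.rpkm_b,
                "M": r.M,
                "A": r.A,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
                "direction": r.direction,
                "zero_in_both": r.zero_in_both,
            }
            for r in results
        ]
    )
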