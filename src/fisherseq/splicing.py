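"""Count-based alternative-splicing statistics for cassette exons and
retained introns.

For a skipped (cassette) exon the test contrasts inclusion reads against
the sum of skipping and flanking reads between two conditions; for a
retained intron it contrasts intronic inclusion reads against flanking
reads.  Both are two-sided Fisher's exact tests on the implied 2x2 table,
Bonferroni-corrected separately per event type over the events testable in
that comparison.

Direction calls and the reported log2 ratio change use a continuity
adjustment of +0.5 per table cell so that ratios are always defined:
skipped exons report the exclusion:inclusion ratio (increased_skipping
when it rises from reference to condition), retained introns the
inclusion:flanking ratio (increased_retention when it rises).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .counting import ClassCounts, EventCounts
from .errors import DataError
from .stats import bonferroni, fisher_two_sided

__all__ = [
    "SpliceResult",
    "skipped_exon_test",
    "retained_intron_test",
    "splice_direction",
    "differential_splicing",
    "splice_results_frame",
    "SKIPPED_EXON",
    "RETAINED_INTRON",
]

SKIPPED_EXON = "skipped_exon"
RETAINED_INTRON = "retained_intron"


@dataclass
class SpliceResult:
    event_id: str
    type: str  # skipped_exon | retained_intron
    ratio_a: float  # continuity-adjusted SE exclusion:inclusion or RI inclusion:flanking
    ratio_b: float
    delta_log2: float  # log2(ratio_a / ratio_b), condition vs reference
    p_raw: float
    p_adj: float
    significant: bool
    direction: str
    counts_a: ClassCounts = ClassCounts()
    counts_b: ClassCounts = ClassCounts()


def _check_counts(*counts: int) -> None:
    if any(c < 0 for c in counts):
        raise DataError("read-class counts must be >= 0")


def skipped_exon_test(
    inclusion_a: int,
    skipping_a: int,
    flanking_a: int,
    inclusion_b: int,
    skipping_b: int,
    flanking_b: int,
) -> float:
    """Two-sided Fisher P on [[incl_a, skip_a+flank_a], [incl_b, skip_b+flank_b]].

    Returns NaN (untestable marker) when all six counts are zero; such
    events are excluded from the Bonferroni m.
    """
    _check_counts(inclusion_a, skipping_a, flanking_a,
                  inclusion_b, skipping_b, flanking_b)
    if not any((inclusion_a, skipping_a, flanking_a,
                inclusion_b, skipping_b, flanking_b)):
        return math.nan
    return fisher_two_sided(
        [[inclusion_a, skipping_a + flanking_a],
         [inclusion_b, skipping_b + flanking_b]]
    )


def retained_intron_test(
    inclusion_a: int, flanking_a: int, inclusion_b: int, flanking_b: int
) -> float:
    """Two-sided Fisher P on [[incl_a, flank_a], [incl_b, flank_b]].

    NaN (untestable) when all four counts are zero.
    """
    _check_counts(inclusion_a, flanking_a, inclusion_b, flanking_b)
    if not any((inclusion_a, flanking_a, inclusion_b, flanking_b)):
        return math.nan
    return fisher_two_sided(
        [[inclusion_a, flanking_a], [inclusion_b, flanking_b]]
    )


def _se_ratio(c: ClassCounts) -> float:
    # exclusion:inclusion with +0.5 per cell of the test table
    return (c.skipping + c.flanking + 0.5) / (c.inclusion + 0.5)


def _ri_ratio(c: ClassCounts) -> float:
    # inclusion:flanking with +0.5 per cell
    return (c.inclusion + 0.5) / (c.flanking + 0.5)


def splice_direction(event_type: str, counts_a: ClassCounts, counts_b: ClassCounts) -> str:
    """Direction of change from reference (b) to condition (a).

    The continuity adjustment guarantees both ratios are defined; equal
    adjusted ratios are reported as the "decreased" label (no rise).
    """
    if event_type == SKIPPED_EXON:
        return (
            "increased_skipping"
            if _se_ratio(counts_a) > _se_ratio(counts_b)
            else "decreased_skipping"
        )
    if event_type == RETAINED_INTRON:
        return (
            "increased_retention"
            if _ri_ratio(counts_a) > _ri_ratio(counts_b)
            else "decreased_retention"
        )
    raise DataError(f"unknown event type {event_type!r}")


def differential_splicing(
    a: EventCounts,
    b: EventCounts,
    event_types: Mapping[str, str],
    alpha: float = 0.05,
) -> list[SpliceResult]:
    """Test every event of condition a vs reference b.

    ``event_types`` maps event_id -> {skipped_exon, retained_intron}.  The
    Bonferroni m is the number of *testable* events per event type in this
    comparison (SE and RI are corrected separately).  Untestable events
    (all relevant counts zero) are omitted from the results.
    """
    shared = sorted(set(a.counts) & set(b.counts))
    raw: dict[str, float] = {}
    for eid in shared:
        etype = event_types.get(eid)
        ca, cb = a.counts[eid], b.counts[eid]
        if etype == SKIPPED_EXON:
            p = skipped_exon_test(ca.inclusion, ca.skipping, ca.flanking,
                                  cb.inclusion, cb.skipping, cb.flanking)
        elif etype == RETAINED_INTRON:
            p = retained_intron_test(ca.inclusion, ca.flanking,
                                     cb.inclusion, cb.flanking)
        else:
            raise DataError(f"event {eid} has no declared type")
        if not math.isnan(p):
            raw[eid] = p

    m_by_type = {
        t: sum(1 for eid in raw if event_types[eid] == t)
        for t in (SKIPPED_EXON, RETAINED_INTRON)
    }
    out: list[SpliceResult] = []
    for eid, p in raw.items():
        etype = event_types[eid]
        ca, cb = a.counts[eid], b.counts[eid]
        ratio_a = _se_ratio(ca) if etype == SKIPPED_EXON else _ri_ratio(ca)
        ratio_b = _se_ratio(cb) if etype == SKIPPED_EXON else _ri_ratio(cb)
        padj = bonferroni(p, m_by_type[etype])
        out.append(
            SpliceResult(
                event_id=eid,
                type=etype,
                ratio_a=ratio_a,
                ratio_b=ratio_b,
                delta_log2=math.log2(ratio_a / ratio_b),
                p_raw=p,
                p_adj=padj,
                significant=padj < alpha,
                direction=splice_direction(etype, ca, cb),
                counts_a=ca,
                counts_b=cb,
            )
        )
    out.sort(key=lambda r: (r.p_raw, r.event_id))
    return out


def splice_results_frame(results: Sequence[SpliceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "type": r.type,
                "inclusion_a": r.counts_a.inclusion,
                "skipping_a": r.counts_a.skipping,
                "flanking_a": r.counts_a.flanking,
                "inclusion_b": r.counts_b.inclusion,
                "skipping_b": r.counts_b.skipping,
                "flanking_b": r.counts_b.flanking,
                "ratio_a": r.ratio_a,
                "ratio_b": r.ratio_b,
                "delta_log2": r.delta_log2,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
                "direction": r.direction,
            }
            for r in results
        ]
    )
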