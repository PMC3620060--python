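"""Read counting: gene-level counts over constitutive exons and per-event
read classes.

The counting universe is reads flagged as uniquely mapped.  A read
increments a gene's count iff at least one aligned base overlaps the gene's
constitutive exons; reads touching constitutive bases of more than one gene
are discarded as ambiguous.  For splicing events, each read is assigned
exactly one class per event (inclusion / skipping / flanking / irrelevant);
a read may count for several distinct events, which are tested
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from intervaltree import IntervalTree

from .annotation import (
    GeneModel,
    GenomicInterval,
    RetainedIntronEvent,
    SkippedExonEvent,
)
from .errors import DataError

__all__ = [
    "ReadAlignment",
    "SampleCounts",
    "ClassCounts",
    "EventCounts",
    "count_gene_reads",
    "classify_read_for_event",
    "count_events",
    "INCLUSION",
    "SKIPPING",
    "FLANKING",
    "IRRELEVANT",
]

INCLUSION = "inclusion"
SKIPPING = "skipping"
FLANKING = "flanking"
IRRELEVANT = "irrelevant"


@dataclass(frozen=True)
class ReadAlignment:
    """Simplified alignment: ordered blocks; gaps between blocks are splice
    junctions."""

    chrom: str
    blocks: tuple[GenomicInterval, ...]
    unique: bool = True

    def __post_init__(self):
        if not self.blocks:
            raise DataError("read with zero aligned blocks")
        object.__setattr__(self, "blocks", tuple(self.blocks))
        for b in self.blocks:
            if b.chrom != self.chrom:
                raise DataError("read blocks on a different chromosome")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise DataError("read blocks overlap or are unsorted")

    def junctions(self) -> list[tuple[int, int]]:
        """(donor, acceptor) coordinate pairs spanned by this read."""
        return [
            (a.end, b.start)
            for a, b in zip(self.blocks, self.blocks[1:])
            if b.start > a.end
        ]


@dataclass
class SampleCounts:
    """Gene-level read counts for one library."""

    condition: str
    total_uniquely_mapped: int
    gene_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.total_uniquely_mapped < 0:
            raise DataError("total_uniquely_mapped must be >= 0")
        if any(c < 0 for c in self.gene_counts.values()):
            raise DataError("gene counts must be >= 0")


class ClassCounts(NamedTuple):
    inclusion: int = 0
    skipping: int = 0
    flanking: int = 0


@dataclass
class EventCounts:
    """Per-event read-class counts for one library.

    By convention retained-intron events have ``skipping == 0``.
    """

    condition: str
    counts: dict[str, ClassCounts] = field(default_factory=dict)

    def __post_init__(self):
        for eid, cc in self.counts.items():
            if min(cc) < 0:
                raise DataError(f"negative class count for event {eid}")


# ---------------------------------------------------------------------------
# gene-level counting
# ---------------------------------------------------------------------------

def count_gene_reads(
    reads: Iterable[ReadAlignment],
    genes: Mapping[str, GeneModel] | Sequence[GeneModel],
    condition: str = "sample",
) -> SampleCounts:
    """Count uniquely mapped reads over constitutive exons.

    Genes must have constitutive exons derived.  Raises on an empty gene
    collection.
    """
    gene_list = list(genes.values()) if isinstance(genes, Mapping) else list(genes)
    if not gene_list:
        raise DataError("empty gene collection")
    trees: dict[str, IntervalTree] = {}
    for g in gene_list:
        if g.constitutive_exons is None:
            raise DataError(
                f"gene {g.gene_id}: constitutive exons not derived"
            )
        for iv in g.constitutive_exons:
            trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, g.gene_id
            )

    counts: dict[str, int] = {g.gene_id: 0 for g in gene_list}
    n_unique = 0
    for read in reads:
        if not read.unique:
            continue
        n_unique += 1
        tree = trees.get(read.chrom)
        if tree is None:
            continue
        hit_genes = {
            hit.data
            for b in read.blocks
            for hit in tree.overlap(b.start, b.end)
        }
        if len(hit_genes) == 1:
            counts[hit_genes.pop()] += 1
        # 0 hits: read outside constitutive exons; >1: ambiguous, discarded
    return SampleCounts(
        condition=condition, total_uniquely_mapped=n_unique, gene_counts=counts
    )


# ---------------------------------------------------------------------------
# event-level classification
# ---------------------------------------------------------------------------

def _overlaps(read: ReadAlignment, iv: GenomicInterval) -> bool:
    return any(b.overlaps(iv) for b in read.blocks)


def classify_read_for_event(
    read: ReadAlignment, event: SkippedExonEvent | RetainedIntronEvent
) -> str:
    """Assign exactly one class to a read with respect to one event.

    Skipped exon: *inclusion* if the read overlaps the cassette body or
    spans an upstream->cassette or cassette->downstream junction;
    *skipping* if it spans the upstream->downstream junction; *flanking* if
    it overlaps an upstream/downstream exon body only and spans no junction
    of the event; otherwise *irrelevant*.

    Retained intron: *inclusion* if the read overlaps intron interior
    bases; *flanking* if it overlaps a flanking exon or spans the spliced
    left->right junction without intronic bases; otherwise *irrelevant*.
    """
    if isinstance(event, SkippedExonEvent):
        u, c, d = event.upstream_exon, event.cassette_exon, event.downstream_exon
        if read.chrom != c.chrom:
            return IRRELEVANT
        juncs = set(read.junctions())
        if (
            _overlaps(read, c)
            or (u.end, c.start) in juncs
            or (c.end, d.start) in juncs
        ):
            return INCLUSION
        if (u.end, d.start) in juncs:
            return SKIPPING
        event_juncs = {(u.end, c.start), (c.end, d.start), (u.end, d.start)}
        if (_overlaps(read, u) or _overlaps(read, d)) and not (
            juncs & event_juncs
        ):
            return FLANKING
        return IRRELEVANT

    intron = event.intron
    if read.chrom != intron.chrom:
        return IRRELEVANT
    if _overlaps(read, intron):
        return INCLUSION
    spliced = (intron.start, intron.end)
    if (
        _overlaps(read, event.left_exon)
        or _overlaps(read, event.right_exon)
        or spliced in set(read.junctions())
    ):
        return FLANKING
    return IRRELEVANT


def _event_span(event: SkippedExonEvent | RetainedIntronEvent) -> GenomicInterval:
    if isinstance(event, SkippedExonEvent):
        return GenomicInterval(
            event.upstream_exon.chrom,
            event.upstream_exon.start,
            event.downstream_exon.end,
        )
    return GenomicInterval(
        event.intron.chrom, event.left_exon.start, event.right_exon.end
    )


def count_events(
    reads: Iterable[ReadAlignment],
    events: Sequence[SkippedExonEvent | RetainedIntronEvent],
    condition: str = "sample",
) -> EventCounts:
    """Aggregate read classes per event over all unique reads."""
    spans = {ev.event_id: _event_span(ev) for ev in events}
    tallies = {ev.event_id: [0, 0, 0] for ev in events}
    for read in reads:
        if not read.unique:
            continue
        for ev in events:
            # cheap span prefilter; classification handles the rest
            if not _overlaps(read, spans[ev.event_id]):
                continue
            cls = classify_read_for_event(read, ev)
            if cls == INCLUSION:
                tallies[ev.event_id][0] += 1
            elif cls == SKIPPING:
                tallies[ev.event_id][1] += 1
            elif cls == FLANKING:
                tallies[ev.event_id][2] += 1
    return EventCounts(
        condition=condition,
        counts={eid: ClassCounts(*t) for eid, t in tallies.items()},
    )
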