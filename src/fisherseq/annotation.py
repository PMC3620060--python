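"""Gene models and the event universe derived from them.

Transcript annotations (GTF/GFF3 or BED12) are turned into per-gene
structures that the downstream statistics operate on:

* **constitutive exons** — the maximal set of genomic bases that are exonic
  in *every* transcript of a gene.  Their summed length is the "exon model"
  length used for RPKM normalisation, and gene-level read counting is
  restricted to these bases so that alternative regions do not bias
  expression estimates.
* **skipped-exon (cassette) events** — exon triples (upstream, cassette,
  downstream) for which the annotation supports both the inclusion isoform
  (all three exons spliced consecutively) and the skipping isoform
  (upstream joined directly to downstream).
* **retained-intron events** — every annotated intron together with its
  flanking exons, deduplicated across transcripts by coordinates.

All coordinates are 0-based half-open internally; GTF/GFF3 input (1-based
inclusive) is converted on read.  Constitutive exons are defined at base
resolution, so partially shared exons contribute their shared bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import gffutils.feature

from .errors import DataError, ParseError

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "SkippedExonEvent",
    "RetainedIntronEvent",
    "load_gene_models",
    "derive_constitutive_exons",
    "enumerate_skipped_exons",
    "enumerate_retained_introns",
    "merge_intervals",
    "intersect_intervals",
    "write_events_tsv",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise DataError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self):
        if not self.exons:
            raise DataError(f"transcript {self.transcript_id} has zero exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise DataError(
                f"transcript {self.transcript_id}: exons span multiple "
                "chromosomes or strands"
            )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise DataError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]


@dataclass
class GeneModel:
    gene_id: str
    symbol: str = ""
    transcripts: list[Transcript] = field(default_factory=list)
    constitutive_exons: list[GenomicInterval] | None = None
    constitutive_length_bp: int | None = None


@dataclass(frozen=True)
class SkippedExonEvent:
    event_id: str
    gene_id: str
    upstream_exon: GenomicInterval
    cassette_exon: GenomicInterval
    downstream_exon: GenomicInterval

    def __post_init__(self):
        u, c, d = self.upstream_exon, self.cassette_exon, self.downstream_exon
        if not (u.end <= c.start < c.end <= d.start):
            raise DataError(
                f"event {self.event_id}: exon triple is not ordered "
                "upstream < cassette < downstream"
            )


@dataclass(frozen=True)
class RetainedIntronEvent:
    event_id: str
    gene_id: str
    intron: GenomicInterval
    left_exon: GenomicInterval
    right_exon: GenomicInterval

    def __post_init__(self):
        if not (
            self.left_exon.end == self.intron.start
            and self.intron.end == self.right_exon.start
        ):
            raise DataError(
                f"event {self.event_id}: intron does not abut its flanking exons"
            )


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or adjacent intervals into maximal disjoint ones."""
    by_chrom: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault((iv.chrom, iv.strand), []).append(iv)
    out: list[GenomicInterval] = []
    for (chrom, strand), ivs in by_chrom.items():
        ivs.sort(key=lambda e: (e.start, e.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    return sorted(out, key=lambda e: (e.chrom, e.start, e.end))


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level intersection of two merged interval sets."""
    out: list[GenomicInterval] = []
    for x in a:
        for y in b:
            if x.chrom != y.chrom:
                continue
            lo, hi = max(x.start, y.start), min(x.end, y.end)
            if lo < hi:
                strand = x.strand if x.strand == y.strand else "."
                out.append(GenomicInterval(x.chrom, lo, hi, strand))
    return merge_intervals(out) if out else []


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_GTF_EXTS = ("gtf", "gff", "gff3")


def load_gene_models(
    stream: TextIO | Iterable[str], fmt: str = "gtf"
) -> dict[str, GeneModel]:
    """Parse an annotation stream into gene models keyed by gene id.

    Parameters
    ----------
    stream:
        Iterable of text lines in the declared dialect.
    fmt:
        ``"gtf"``/``"gff3"`` (exon features must carry gene and transcript
        identifiers, directly or through ``Parent`` links) or ``"bed12"``
        (one transcript per line; a ``name`` field of the form
        ``gene|transcript`` groups transcripts into genes, otherwise the
        name is both gene and transcript id).

    Constitutive fields of the returned models are not yet populated; call
    :func:`derive_constitutive_exons`.
    """
    fmt = fmt.lower()
    if fmt in _GTF_EXTS:
        return _load_gff(stream, fmt)
    if fmt == "bed12":
        return _load_bed12(stream)
    raise ParseError(f"unknown annotation format {fmt!r}")


def _load_gff(stream: Iterable[str], fmt: str) -> dict[str, GeneModel]:
    exons: dict[str, list[tuple[str, int, int, str]]] = {}  # transcript -> exons
    tx_gene: dict[str, str] = {}
    tx_parent: dict[str, str] = {}  # GFF3 transcript -> gene feature id
    gene_symbol: dict[str, str] = {}
    exon_parents: dict[str, list[str]] = {}

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if line.count("\t") != 8:
            raise ParseError(
                f"malformed record: expected 9 tab-separated fields, "
                f"got {line.count(chr(9)) + 1}", lineno)
        try:
            feat = gffutils.feature.feature_from_line(line)
        except Exception as exc:  # noqa: BLE001 - gffutils raises plain errors
            raise ParseError(f"malformed record: {exc}", lineno) from exc
        ftype = feat.featuretype.lower()
        attrs = feat.attributes
        if ftype in {"mrna", "transcript"}:
            tid = _first(attrs, "transcript_id") or _first(attrs, "ID")
            gid = _first(attrs, "gene_id") or _first(attrs, "Parent")
            if tid and gid:
                tx_parent[tid] = gid
        elif ftype == "gene":
            gid = _first(attrs, "gene_id") or _first(attrs, "ID")
            sym = _first(attrs, "gene_name") or _first(attrs, "Name") or ""
            if gid:
                gene_symbol[gid] = sym
        elif ftype == "exon":
            if feat.end < feat.start:
                raise ParseError(
                    f"exon with end < start ({feat.start}-{feat.end})", lineno
                )
            tids = attrs.get("transcript_id") or attrs.get("Parent")
            if not tids:
                raise ParseError("exon without transcript_id/Parent", lineno)
            for tid in tids:
                exons.setdefault(tid, []).append(
                    # GTF/GFF3 are 1-based inclusive; convert to 0-based half-open
                    (feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
                )
            gid = _first(attrs, "gene_id")
            if gid:
                for tid in tids:
                    tx_gene[tid] = gid
                sym = _first(attrs, "gene_name")
                if sym:
                    gene_symbol[gid] = sym
            exon_parents.setdefault(lineno, list(tids))

    genes: dict[str, GeneModel] = {}
    for tid, blocks in exons.items():
        gid = tx_gene.get(tid) or tx_parent.get(tid)
        if gid is None:
            raise ParseError(
                f"exons of transcript {tid} carry no gene identifier"
            )
        ivs = [GenomicInterval(c, s, e, st) for (c, s, e, st) in blocks]
        tx = Transcript(transcript_id=tid, gene_id=gid, exons=ivs)
        genes.setdefault(
            gid, GeneModel(gene_id=gid, symbol=gene_symbol.get(gid, ""))
        ).transcripts.append(tx)
    for g in genes.values():
        g.transcripts.sort(key=lambda t: t.transcript_id)
    return genes


def _first(attrs, key: str) -> str | None:
    vals = attrs.get(key)
    if not vals:
        return None
    # GFF3 Parent may be "transcript:ENST..."; strip a leading type prefix
    return re.sub(r"^[A-Za-z]+:", "", vals[0])


def _load_bed12(stream: Iterable[str]) -> dict[str, GeneModel]:
    genes: dict[str, GeneModel] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(
                f"BED12 record has {len(fields)} fields (12 required)", lineno
            )
        try:
            chrom = fields[0]
            start = int(fields[1])
            name = fields[3]
            strand = fields[5] if fields[5] in {"+", "-"} else "."
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].split(",") if x]
            offsets = [int(x) for x in fields[11].split(",") if x]
        except ValueError as exc:
            raise ParseError(f"malformed BED12 numeric field: {exc}", lineno) from exc
        if not (len(sizes) == len(offsets) == n_blocks):
            raise ParseError("blockCount does not match block lists", lineno)
        if n_blocks == 0:
            raise ParseError(f"transcript {name} has zero exons", lineno)
        if "|" in name:
            gid, tid = name.split("|", 1)
        else:
            gid = tid = name
        try:
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
        except DataError as exc:
            raise ParseError(str(exc), lineno) from exc
        tx = Transcript(transcript_id=tid, gene_id=gid, exons=exons)
        genes.setdefault(gid, GeneModel(gene_id=gid)).transcripts.append(tx)
    for g in genes.values():
        g.transcripts.sort(key=lambda t: t.transcript_id)
    return genes


# ---------------------------------------------------------------------------
# derivations
# ---------------------------------------------------------------------------

def derive_constitutive_exons(gene: GeneModel) -> GeneModel:
    """Populate constitutive exons: bases exonic in every transcript.

    Returns the same (mutated) model for chaining.  An empty result is
    legal; such genes have no RPKM and are excluded downstream.
    """
    if not gene.transcripts:
        raise DataError(f"gene {gene.gene_id} has no transcripts")
    current = merge_intervals(gene.transcripts[0].exons)
    for tx in gene.transcripts[1:]:
        current = intersect_intervals(current, merge_intervals(tx.exons))
        if not current:
            break
    gene.constitutive_exons = current
    gene.constitutive_length_bp = sum(len(iv) for iv in current)
    return gene


def enumerate_skipped_exons(gene: GeneModel) -> list[SkippedExonEvent]:
    """Cassette events supported by both an inclusion and a skipping isoform.

    Inclusion requires some transcript to splice upstream->cassette->downstream
    consecutively; skipping requires some transcript to splice
    upstream->downstream consecutively.  Exons are matched by exact
    coordinates.
    """
    key = lambda iv: (iv.start, iv.end)  # noqa: E731
    inclusion_triples: set[tuple] = set()
    junctions: set[tuple] = set()  # consecutive exon pairs
    exon_by_key: dict[tuple, GenomicInterval] = {}
    for tx in gene.transcripts:
        ex = tx.exons
        for iv in ex:
            exon_by_key[key(iv)] = iv
        for a, b in zip(ex, ex[1:]):
            junctions.add((key(a), key(b)))
        for a, b, c in zip(ex, ex[1:], ex[2:]):
            inclusion_triples.add((key(a), key(b), key(c)))

    events = []
    for (u, c, d) in sorted(inclusion_triples):
        if (u, d) in junctions:
            uu, cc, dd = exon_by_key[u], exon_by_key[c], exon_by_key[d]
            eid = (
                f"SE:{uu.chrom}:{uu.start}-{uu.end}:"
                f"{cc.start}-{cc.end}:{dd.start}-{dd.end}"
            )
            events.append(
                SkippedExonEvent(
                    event_id=eid,
                    gene_id=gene.gene_id,
                    upstream_exon=uu,
                    cassette_exon=cc,
                    downstream_exon=dd,
                )
            )
    events.sort(key=lambda e: (e.cassette_exon.chrom, e.cassette_exon.start,
                               e.cassette_exon.end, e.event_id))
    return events


def enumerate_retained_introns(gene: GeneModel) -> list[RetainedIntronEvent]:
    """One event per annotated intron, deduplicated by coordinates."""
    seen: dict[tuple, RetainedIntronEvent] = {}
    for tx in gene.transcripts:
        for left, right in zip(tx.exons, tx.exons[1:]):
            if right.start <= left.end:
                continue
            k = (tx.chrom, left.end, right.start)
            if k in seen:
                continue
            intron = GenomicInterval(tx.chrom, left.end, right.start, tx.strand)
            eid = f"RI:{tx.chrom}:{intron.start}-{intron.end}"
            seen[k] = RetainedIntronEvent(
                event_id=eid,
                gene_id=gene.gene_id,
                intron=intron,
                left_exon=left,
                right_exon=right,
            )
    return sorted(seen.values(), key=lambda e: (e.intron.chrom, e.intron.start,
                                                e.intron.end))


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_events_tsv(
    events: Iterable[SkippedExonEvent | RetainedIntronEvent], out: TextIO
) -> None:
    """Write the event universe as a TSV (event_id, gene_id, type, coordinates)."""
    out.write("event_id\tgene_id\ttype\tcoordinates\n")
    for ev in events:
        if isinstance(ev, SkippedExonEvent):
            etype = "skipped_exon"
            u, c, d = ev.upstream_exon, ev.cassette_exon, ev.downstream_exon
            coords = (
                f"{c.chrom}:{u.start}-{u.end},{c.start}-{c.end},{d.start}-{d.end}"
            )
        else:
            etype = "retained_intron"
            coords = f"{ev.intron.chrom}:{ev.intron.start}-{ev.intron.end}"
        out.write(f"{ev.event_id}\t{ev.gene_id}\t{etype}\t{coords}\n")


def iter_all_events(
    genes: Iterable[GeneModel],
) -> Iterator[SkippedExonEvent | RetainedIntronEvent]:
    for g in genes:
        yield from enumerate_skipped_exons(g)
        yield from enumerate_retained_introns(g)
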