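"""TSV file contracts shared by the pipeline stages.

Gene count table::

    #total_uniquely_mapped<TAB>1000000<TAB>1000000...
    gene_id<TAB>vector<TAB>wildtype...
    G00001<TAB>512<TAB>498...

The comment line carries library totals aligned with the condition columns
of the header.  Event count tables have three columns per condition
(``{cond}.inclusion``, ``{cond}.skipping``, ``{cond}.flanking``).  All
files are UTF-8, tab-separated, with deterministic row order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, TextIO

import pandas as pd

from .counting import ClassCounts, EventCounts, SampleCounts
from .errors import ParseError

__all__ = [
    "write_gene_counts",
    "read_gene_counts",
    "write_event_counts",
    "read_event_counts",
    "write_gene_lengths",
    "read_gene_lengths",
    "write_tsv",
    "write_json",
]

TOTALS_TAG = "#total_uniquely_mapped"


def write_gene_counts(samples: Mapping[str, SampleCounts], out: TextIO) -> None:
    conds = list(samples)
    totals = "\t".join(str(samples[c].total_uniquely_mapped) for c in conds)
    out.write(f"{TOTALS_TAG}\t{totals}\n")
    out.write("gene_id\t" + "\t".join(conds) + "\n")
    gene_ids = sorted(set().union(*(samples[c].gene_counts for c in conds)))
    for gid in gene_ids:
        row = "\t".join(str(samples[c].gene_counts.get(gid, 0)) for c in conds)
        out.write(f"{gid}\t{row}\n")


def read_gene_counts(stream: TextIO) -> dict[str, SampleCounts]:
    first = stream.readline().rstrip("\n")
    if not first.startswith(TOTALS_TAG):
        raise ParseError(
            f"gene count table must start with a {TOTALS_TAG} line", 1)
    totals = [int(x) for x in first.split("\t")[1:]]
    header = stream.readline().rstrip("\n").split("\t")
    if header[0] != "gene_id":
        raise ParseError("second line must be the gene_id header", 2)
    conds = header[1:]
    if len(totals) != len(conds):
        raise ParseError("library totals do not match condition columns", 1)
    counts: dict[str, dict[str, int]] = {c: {} for c in conds}
    for lineno, line in enumerate(stream, start=3):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(conds) + 1:
            raise ParseError("wrong number of columns", lineno)
        for c, v in zip(conds, fields[1:]):
            counts[c][fields[0]] = int(v)
    return {
        c: SampleCounts(condition=c, total_uniquely_mapped=t, gene_counts=counts[c])
        for c, t in zip(conds, totals)
    }


def write_event_counts(
    events: Mapping[str, EventCounts], event_types: Mapping[str, str], out: TextIO
) -> None:
    conds = list(events)
    cols = [f"{c}.{cls}" for c in conds
            for cls in ("inclusion", "skipping", "flanking")]
    out.write("event_id\ttype\t" + "\t".join(cols) + "\n")
    event_ids = sorted(set().union(*(events[c].counts for c in conds)))
    for eid in event_ids:
        vals = []
        for c in conds:
            cc = events[c].counts.get(eid, ClassCounts())
            vals += [str(cc.inclusion), str(cc.skipping), str(cc.flanking)]
        out.write(f"{eid}\t{event_types[eid]}\t" + "\t".join(vals) + "\n")


def read_event_counts(
    stream: TextIO,
) -> tuple[dict[str, EventCounts], dict[str, str]]:
    header = stream.readline().rstrip("\n").split("\t")
    if header[:2] != ["event_id", "type"]:
        raise ParseError("event table header must start event_id<TAB>type", 1)
    conds = []
    for col in header[2::3]:
        if not col.endswith(".inclusion"):
            raise ParseError(f"unexpected column {col!r}", 1)
        conds.append(col[: -len(".inclusion")])
    counts: dict[str, dict[str, ClassCounts]] = {c: {} for c in conds}
    types: dict[str, str] = {}
    for lineno, line in enumerate(stream, start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2 + 3 * len(conds):
            raise ParseError("wrong number of columns", lineno)
        eid, etype = fields[0], fields[1]
        types[eid] = etype
        for i, c in enumerate(conds):
            i0 = 2 + 3 * i
            counts[c][eid] = ClassCounts(
                int(fields[i0]), int(fields[i0 + 1]), int(fields[i0 + 2]))
    return (
        {c: EventCounts(condition=c, counts=counts[c]) for c in conds},
        types,
    )


def write_gene_lengths(lengths: Mapping[str, int], out: TextIO) -> None:
    out.write("gene_id\tconstitutive_length_bp\n")
    for gid in sorted(lengths):
        out.write(f"{gid}\t{lengths[gid]}\n")


def read_gene_lengths(stream: TextIO) -> dict[str, int]:
    header = stream.readline().rstrip("\n").split("\t")
    if header != ["gene_id", "constitutive_length_bp"]:
        raise ParseError("unexpected gene length table header", 1)
    out = {}
    for lineno, line in enumerate(stream, start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ParseError("wrong number of columns", lineno)
        out[fields[0]] = int(fields[1])
    return out


def write_tsv(frame: pd.DataFrame, path: str | Path,
              params: Mapping | None = None) -> None:
    """Write a results table with an optional header comment recording
    parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if params:
            fh.write("# " + json.dumps(params, sort_keys=True, default=str) + "\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
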