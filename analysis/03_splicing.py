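#!/usr/bin/env python
"""Cassette-exon and retained-intron statistics per condition vs vector.

Reads the event-class count tables from 01_simulate.py, runs the
inclusion-vs-(skipping+flanking) and inclusion-vs-flanking Fisher tests
with per-event-type Bonferroni selection, and writes one results table per
comparison.
"""

import argparse
from pathlib import Path

from fisherseq.io import read_event_counts, write_tsv
from fisherseq.splicing import (RETAINED_INTRON, SKIPPED_EXON,
                                differential_splicing, splice_results_frame)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--experiment-dir", type=Path,
                    default=Path("results/analysis/experiment"))
    ap.add_argument("--out-dir", type=Path,
                    default=Path("results/analysis/splicing"))
    ap.add_argument("--reference", default="vector")
    args = ap.parse_args()

    with open(args.experiment_dir / "event_counts.tsv") as fh:
        events, event_types = read_event_counts(fh)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    ref = args.reference
    for cond in (c for c in events if c != ref):
        results = differential_splicing(events[cond], events[ref], event_types)
        frame = splice_results_frame(results)
        write_tsv(frame, args.out_dir / f"splice_{cond}_vs_{ref}.tsv",
                  params={"alpha": 0.05, "correction": "bonferroni per type"})
        for etype in (SKIPPED_EXON, RETAINED_INTRON):
            sub = frame[frame["type"] == etype]
            n_sig = int(sub["significant"].sum())
            dirs = sub.loc[sub["significant"], "direction"].value_counts()
            summary = ", ".join(f"{k}={v}" for k, v in dirs.items()) or "-"
            print(f"{cond:10s} vs {ref} [{etype:15s}]: "
                  f"{n_sig:3d}/{len(sub)} significant ({summary})")


if __name__ == "__main__":
    main()
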