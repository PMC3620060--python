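#!/usr/bin/env python
"""Condition-similarity inference on the simulated experiment.

For each mutant-like condition, counts differentially expressed genes
against the overexpression and knock-down references, tests the 2x2
similarity contingency and calls the gain/loss-of-function verdict; then
contrasts the two mutant-like conditions' up/down balance (direction
contingency) and tabulates the Venn regions of the per-condition
significant sets.
"""

import argparse
import json
from pathlib import Path

from fisherseq.comparison import (contingency_report, direction_contingency,
                                  gain_loss_verdict, significant_set,
                                  venn_regions)
from fisherseq.expression import differential_expression
from fisherseq.io import read_gene_counts, read_gene_lengths, write_json


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--experiment-dir", type=Path,
                    default=Path("results/analysis/experiment"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/analysis/similarity.json"))
    ap.add_argument("--reference", default="vector")
    ap.add_argument("--overexpression", default="wildtype")
    ap.add_argument("--knockdown", default="siRNA")
    ap.add_argument("--mutants", nargs="+", default=["R521G", "R522G"])
    args = ap.parse_args()

    with open(args.experiment_dir / "gene_counts.tsv") as fh:
        samples = read_gene_counts(fh)
    with open(args.experiment_dir / "gene_lengths.tsv") as fh:
        lengths = read_gene_lengths(fh)

    report = {"contingencies": [], "verdicts": {}}
    contingencies = []

    for mutant in args.mutants:
        counts = {}
        for label, other in (("overexpression", args.overexpression),
                             ("knockdown", args.knockdown)):
            results = differential_expression(samples[mutant], samples[other],
                                              lengths)
            n_sig = sum(r.significant for r in results)
            counts[label] = (n_sig, len(results) - n_sig)
        verdict, ctg = gain_loss_verdict(counts["overexpression"],
                                         counts["knockdown"])
        report["verdicts"][mutant] = verdict
        contingencies.append(ctg)
        print(f"{mutant}: DE vs {args.overexpression} "
              f"{counts['overexpression'][0]}, vs {args.knockdown} "
              f"{counts['knockdown'][0]} (p={ctg.p:.3g}) -> {verdict}")

    de_vs_ref = {
        cond: differential_expression(samples[cond], samples[args.reference],
                                      lengths)
        for cond in samples if cond != args.reference
    }
    sig_sets = {c: significant_set(r) for c, r in de_vs_ref.items()}

    m1, m2 = args.mutants[:2]
    ups = {m: sum(r.significant and r.direction == "up" for r in de_vs_ref[m])
           for m in (m1, m2)}
    ctg = direction_contingency(ups[m1], len(sig_sets[m1]) - ups[m1],
                                ups[m2], len(sig_sets[m2]) - ups[m2],
                                labels=(m1, m2))
    contingencies.append(ctg)
    print(f"direction contrast {m1} ({ups[m1]} up / "
          f"{len(sig_sets[m1]) - ups[m1]} down) vs {m2} ({ups[m2]} up / "
          f"{len(sig_sets[m2]) - ups[m2]} down): p={ctg.p:.3g}")

    venn = venn_regions(sig_sets)
    shared_all = venn.region_counts[frozenset(sig_sets)]
    print(f"genes significant in every condition vs {args.reference}: "
          f"{shared_all}")

    report["contingencies"] = contingency_report(contingencies)
    report["venn_counts"] = {"&".join(sorted(k)): v
                             for k, v in venn.region_counts.items()}
    write_json(report, args.out)
    print(f"report -> {args.out}")


if __name__ == "__main__":
    main()
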