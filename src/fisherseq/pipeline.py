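"""End-to-end orchestration: counts -> DE -> splicing -> comparison ->
enrichment, with fixed file contracts.

The pipeline consumes either a simulation config (synthetic experiment) or
previously written count tables, runs every pairwise comparison against
the reference condition, and derives the comparison layer: Venn regions
of significant sets, similarity/direction contingencies and the
gain/loss-of-function verdict for designated mutant-like conditions.
Outputs are deterministic given config + seed.
"""

from __future__ import annotations

import json
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .comparison import (
    contingency_report,
    direction_contingency,
    gain_loss_verdict,
    significant_set,
    venn_regions,
)
from .enrichment import GeneSetCollection, enrich, read_gmt
from .errors import ConfigError
from .expression import de_results_frame, differential_expression
from .io import (
    read_event_counts,
    read_gene_counts,
    read_gene_lengths,
    write_event_counts,
    write_gene_counts,
    write_gene_lengths,
    write_json,
    write_tsv,
)
from .simulate import SimulationConfig, simulate_experiment
from .splicing import RETAINED_INTRON, SKIPPED_EXON, differential_splicing, \
    splice_results_frame

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str | Path = "results"
    # exactly one input mode: a simulation config, or count tables
    simulation: SimulationConfig | None = None
    gene_counts_path: str | Path | None = None
    gene_lengths_path: str | Path | None = None
    event_counts_path: str | Path | None = None
    # condition roles
    reference: str = "vector"
    overexpression: str | None = "wildtype"
    knockdown: str | None = "siRNA"
    mutants: tuple[str, ...] = ("R521G", "R522G")
    # thresholds
    alpha: float = 0.05
    # enrichment inputs (optional)
    gmt_path: str | Path | None = None
    seed: int | None = None

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha {self.alpha} outside (0, 1)")
        if (self.simulation is None) == (self.gene_counts_path is None):
            raise ConfigError(
                "exactly one of simulation / gene_counts_path is required")
        for name in ("gene_counts_path", "gene_lengths_path",
                     "event_counts_path", "gmt_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name}: no such file {p}")
        if self.gene_counts_path is not None and self.gene_lengths_path is None:
            raise ConfigError(
                "gene_lengths_path is required with gene_counts_path")


def _log(msg: str) -> None:
    print(f"[fisherseq] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle under ``config.out_dir``.

    Returns a summary dict (also written as ``report.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.simulation is not None:
            sim = config.simulation
            if config.seed is not None:
                sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
            _log(f"simulating experiment (seed={sim.seed})")
            expt = simulate_experiment(sim)
            samples, lengths = expt.samples, expt.gene_lengths
            events, event_types = expt.events, expt.event_types
            with open(out / "gene_counts.tsv", "w") as fh:
                write_gene_counts(samples, fh)
            with open(out / "gene_lengths.tsv", "w") as fh:
                write_gene_lengths(lengths, fh)
            with open(out / "event_counts.tsv", "w") as fh:
                write_event_counts(events, event_types, fh)
            write_tsv(expt.gene_truth, out / "gene_truth.tsv")
            write_tsv(expt.event_truth, out / "event_truth.tsv")
        else:
            with open(config.gene_counts_path) as fh:
                samples = read_gene_counts(fh)
            with open(config.gene_lengths_path) as fh:
                lengths = read_gene_lengths(fh)
            events, event_types = {}, {}
            if config.event_counts_path is not None:
                with open(config.event_counts_path) as fh:
                    events, event_types = read_event_counts(fh)

        ref = config.reference
        if ref not in samples:
            raise ConfigError(f"reference condition {ref!r} not in counts")
        conditions = [c for c in samples if c != ref]

        stage = "differential_expression"
        de_results = {}
        for cond in conditions:
            _log(f"DE: {cond} vs {ref}")
            de_results[cond] = differential_expression(
                samples[cond], samples[ref], lengths, alpha=config.alpha)
            write_tsv(
                de_results_frame(de_results[cond]),
                out / f"de_{cond}_vs_{ref}.tsv",
                params={"condition": cond, "reference": ref,
                        "alpha": config.alpha, "correction": "bonferroni",
                        "log_base": 2},
            )

        stage = "splicing"
        splice_results = {}
        if events:
            for cond in conditions:
                _log(f"splicing: {cond} vs {ref}")
                splice_results[cond] = differential_splicing(
                    events[cond], events[ref], event_types, alpha=config.alpha)
                write_tsv(
                    splice_results_frame(splice_results[cond]),
                    out / f"splice_{cond}_vs_{ref}.tsv",
                    params={"condition": cond, "reference": ref,
                            "alpha": config.alpha, "correction": "bonferroni"},
                )

        stage = "comparison"
        report: dict = {"version": __version__, "alpha": config.alpha,
                        "reference": ref}
        sig_sets = {c: significant_set(de_results[c]) for c in conditions}
        if len(conditions) >= 2:
            venn = venn_regions({c: sig_sets[c] for c in conditions[:5]})
            report["venn_de"] = {
                "&".join(sorted(k)): sorted(v)
                for k, v in venn.region_members.items()
            }
        contingencies = []
        verdicts = {}
        oe, kd = config.overexpression, config.knockdown
        for mutant in config.mutants:
            if mutant not in samples or oe not in samples or kd not in samples:
                continue
            _log(f"similarity inference for {mutant}")
            vs_oe = differential_expression(
                samples[mutant], samples[oe], lengths, alpha=config.alpha)
            vs_kd = differential_expression(
                samples[mutant], samples[kd], lengths, alpha=config.alpha)
            n_sig_oe = sum(r.significant for r in vs_oe)
            n_sig_kd = sum(r.significant for r in vs_kd)
            verdict, ctg = gain_loss_verdict(
                (n_sig_oe, len(vs_oe) - n_sig_oe),
                (n_sig_kd, len(vs_kd) - n_sig_kd),
                alpha=config.alpha,
            )
            verdicts[mutant] = verdict
            contingencies.append(ctg)
        if len(config.mutants) >= 2 and all(
                m in sig_sets for m in config.mutants[:2]):
            m1, m2 = config.mutants[:2]
            ups = {
                m: sum(1 for r in de_results[m]
                       if r.significant and r.direction == "up")
                for m in (m1, m2)
            }
            ctg = direction_contingency(
                ups[m1], len(sig_sets[m1]) - ups[m1],
                ups[m2], len(sig_sets[m2]) - ups[m2],
                labels=(m1, m2),
            )
            contingencies.append(ctg)
            report["mutant_direction_p"] = None if math.isnan(ctg.p) else ctg.p
        report["verdicts"] = verdicts
        report["contingencies"] = contingency_report(contingencies)
        report["n_significant_de"] = {c: len(sig_sets[c]) for c in conditions}
        if splice_results:
            report["n_significant_splice"] = {
                c: {
                    t: sum(1 for r in splice_results[c]
                           if r.significant and r.type == t)
                    for t in (SKIPPED_EXON, RETAINED_INTRON)
                }
                for c in conditions
            }

        stage = "enrichment"
        if config.gmt_path is not None:
            with open(config.gmt_path) as fh:
                sets = read_gmt(fh)
            background = set(lengths)
            collection = GeneSetCollection(sets=sets, background=background)
            enrichment_summary = {}
            for cond in conditions:
                if not sig_sets[cond]:
                    continue
                results = enrich(sig_sets[cond], collection, method="ease")
                write_tsv(
                    pd.DataFrame([r.__dict__ for r in results]),
                    out / f"enrich_{cond}_vs_{ref}.tsv",
                    params={"method": "ease", "background": "tested genes"},
                )
                enrichment_summary[cond] = results[0].set_name if results else None
            report["top_enriched_set"] = enrichment_summary

        write_json(report, out / "report.json")
        run_log = {
            "package": "fisherseq",
            "version": __version__,
            "python": sys.version.split()[0],
            "parameters": {
                "alpha": config.alpha,
                "reference": ref,
                "seed": config.seed
                if config.seed is not None
                else (config.simulation.seed if config.simulation else None),
            },
        }
        write_json(run_log, out / "run_log.json")
        return report
    except ConfigError:
        raise
    except Exception as exc:
        exc.args = (f"[stage: {stage}] {exc}",) + exc.args[1:]
        raise


def pipeline_config_from_json(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig (with optional nested simulation block) from
    JSON."""
    with open(path) as fh:
        raw = json.load(fh)
    sim = raw.pop("simulation", None)
    if sim is not None:
        if "conditions" in sim:
            sim["conditions"] = tuple(sim["conditions"])
        sim = SimulationConfig(**sim)
    if "mutants" in raw:
        raw["mutants"] = tuple(raw["mutants"])
    return PipelineConfig(simulation=sim, **raw)
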