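"""Synthetic five-condition transcriptome experiment with ground truth.

The generator emulates the structure of a transfection experiment measured
by RNA-seq without replicates: an empty-vector reference, an
overexpression condition, two mutant-like conditions and an siRNA
knock-down, one library each.  A designated focal gene carries the
transfection effect itself (~2-fold up in overexpression and mutant
conditions, ~4-fold down under knock-down).  Each non-reference condition
additionally perturbs a configurable fraction of genes with log2
fold-changes of configurable magnitude and up/down bias, and mutant-like
conditions can share a configurable fraction of their perturbed genes
(with identical effects) with another condition — the structure that the
similarity inference is meant to recover.

Counts are drawn per gene and condition from a negative binomial with
configurable dispersion (Poisson at dispersion 0, the default: a single
library per condition measures technical counting noise only).  Splicing
events draw class counts from per-event multinomials whose inclusion
proportion is shifted on the log-odds scale for affected events.

Scale defaults are desk-sized: 2,000 genes and 1e6-read libraries versus
roughly 17,000 genes and 24-31 million reads in a full experiment; event
counts are 200 + 200 versus tens of thousands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import ClassCounts, EventCounts, SampleCounts
from .errors import ConfigError, DataError
from .splicing import RETAINED_INTRON, SKIPPED_EXON

__all__ = ["SimulationConfig", "SimulatedExperiment", "simulate_experiment",
           "recovery_report"]

DEFAULT_CONDITIONS = ("vector", "wildtype", "R521G", "R522G", "siRNA")


def _broadcast(value, conditions, fill: float = 0.0, zero_for: str | None = None):
    """Expand a scalar, or fill missing keys of a mapping, per condition."""
    if isinstance(value, Mapping):
        out = {c: float(value.get(c, fill)) for c in conditions}
    else:
        out = {c: float(value) for c in conditions}
    if zero_for is not None:
        out[zero_for] = 0.0
    return out


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment; the seed fixes all output."""

    n_genes: int = 2000
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    reference: str = "vector"
    library_size: int | Mapping[str, int] = 1_000_000
    # fraction of uniquely mapped reads assigned to constitutive exons
    assigned_fraction: float = 0.7
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 2.0
    length_log2_mean: float = 10.5  # exon-model length ~ 1.4 kb median
    length_log2_sd: float = 0.8
    focal_gene: str = "FUS"
    focal_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"wildtype": 2.0, "R521G": 2.0,
                                 "R522G": 2.0, "siRNA": 0.25}
    )
    de_fraction: float | Mapping[str, float] | None = None
    up_bias: float | Mapping[str, float] | None = None
    effect_log2fc_range: tuple[float, float] = (1.0, 3.0)
    # condition -> (source condition, fraction of DE genes copied from it)
    effect_overlap: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: {"R521G": ("wildtype", 0.9),
                                 "R522G": ("wildtype", 0.9)}
    )
    n_se_events: int = 200
    n_ri_events: int = 200
    splice_effect_fraction: float | Mapping[str, float] = 0.1
    inclusion_shift: float = 1.5  # log-odds magnitude for affected events
    mean_event_reads: float = 100.0
    flanking_fraction: float = 0.2
    dispersion: float = 0.0  # NB dispersion; 0 -> Poisson
    seed: int = 0

    def __post_init__(self):
        conds = tuple(self.conditions)
        self.conditions = conds

        if self.de_fraction is None:
            self.de_fraction = {
                c: 0.0 if c == self.reference else (0.08 if c == "siRNA" else 0.05)
                for c in conds
            }
        else:
            self.de_fraction = _broadcast(self.de_fraction, conds,
                                          zero_for=self.reference)

        if self.up_bias is None:
            defaults = {"R521G": 0.9, "R522G": 0.1}
            self.up_bias = {c: defaults.get(c, 0.5) for c in conds}
        else:
            self.up_bias = _broadcast(self.up_bias, conds, fill=0.5)

        self.splice_effect_fraction = _broadcast(
            self.splice_effect_fraction, conds, zero_for=self.reference)

        if isinstance(self.library_size, Mapping):
            self.library_size = {c: int(self.library_size[c]) for c in conds}
        else:
            self.library_size = {c: int(self.library_size) for c in conds}
        self.validate()
    def validate(self) -> None:
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2")
        if self.reference not in self.conditions:
            raise ConfigError(f"reference {self.reference!r} not in conditions")
        if any(v <= 0 for v in self.library_size.values()):
            raise ConfigError("library_size must be > 0")
        for name, frac_map in (("de_fraction", self.de_fraction),
                               ("up_bias", self.up_bias),
                               ("splice_effect_fraction",
                                self.splice_effect_fraction)):
            for c, v in frac_map.items():
                if not (0.0 <= v <= 1.0):
                    raise ConfigError(f"{name}[{c}]={v} outside [0, 1]")
        if not (0.0 < self.assigned_fraction <= 1.0):
            raise ConfigError("assigned_fraction must be in (0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        lo, hi = self.effect_log2fc_range
        if not (0 < lo <= hi):
            raise ConfigError("effect_log2fc_range must satisfy 0 < lo <= hi")
        if not (0.0 < self.flanking_fraction < 1.0):
            raise ConfigError("flanking_fraction must be in (0, 1)")
        for c, (src, frac) in self.effect_overlap.items():
            if c in self.conditions and src not in self.conditions:
                raise ConfigError(
                    f"effect_overlap[{c}] source {src!r} not in conditions")
            if not (0.0 <= frac <= 1.0):
                raise ConfigError(f"effect_overlap[{c}] fraction outside [0, 1]")


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    gene_lengths: dict[str, int]
    samples: dict[str, SampleCounts]
    events: dict[str, EventCounts]
    event_types: dict[str, str]
    gene_truth: pd.DataFrame   # gene_id, condition, is_de, true_direction, true_log2fc
    event_truth: pd.DataFrame  # event_id, type, condition, is_changed, true_direction


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float
               ) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Draw one fully labelled synthetic experiment from the config seed."""
    rng = np.random.default_rng(config.seed)
    conds = list(config.conditions)
    ref = config.reference

    gene_ids = [config.focal_gene] + [
        f"G{i:05d}" for i in range(1, config.n_genes)
    ]
    weights = 2.0 ** rng.normal(config.baseline_log2_mean,
                                config.baseline_log2_sd, config.n_genes)
    proportions = weights / weights.sum()
    lengths = np.maximum(
        100,
        np.round(2.0 ** rng.normal(config.length_log2_mean,
                                   config.length_log2_sd,
                                   config.n_genes)).astype(int),
    )
    gene_lengths = dict(zip(gene_ids, lengths.tolist()))
    idx = {g: i for i, g in enumerate(gene_ids)}

    # --- per-condition log2 effects -------------------------------------
    log2fc: dict[str, np.ndarray] = {c: np.zeros(config.n_genes) for c in conds}
    eligible = np.arange(1, config.n_genes)  # focal gene handled separately
    de_sets: dict[str, np.ndarray] = {}
    lo, hi = config.effect_log2fc_range

    def _draw_effects(cond: str, genes: np.ndarray) -> None:
        signs = np.where(rng.random(genes.size) < config.up_bias[cond], 1.0, -1.0)
        mags = rng.uniform(lo, hi, genes.size)
        log2fc[cond][genes] = signs * mags

    # source conditions first so overlapped conditions can copy their effects
    overlap = {c: so for c, so in config.effect_overlap.items() if c in conds}
    sources = [c for c in conds if c not in overlap]
    for cond in sources + list(overlap):
        n_de = int(round(config.de_fraction[cond] * config.n_genes))
        if n_de == 0:
            de_sets[cond] = np.array([], dtype=int)
            continue
        if cond in overlap:
            src, frac = overlap[cond]
            src_set = de_sets.get(src, np.array([], dtype=int))
            n_shared = min(int(round(frac * n_de)), src_set.size)
            shared = rng.choice(src_set, n_shared, replace=False) \
                if n_shared else np.array([], dtype=int)
            pool = np.setdiff1d(eligible, shared, assume_unique=False)
            fresh = rng.choice(pool, n_de - n_shared, replace=False)
            log2fc[cond][shared] = log2fc[src][shared]
            _draw_effects(cond, fresh)
            de_sets[cond] = np.concatenate([shared, fresh])
        else:
            genes = rng.choice(eligible, n_de, replace=False)
            _draw_effects(cond, genes)
            de_sets[cond] = genes

    for cond, mult in config.focal_multipliers.items():
        if cond in conds and mult != 1.0:
            log2fc[cond][idx[config.focal_gene]] = np.log2(mult)

    # --- gene counts -----------------------------------------------------
    samples: dict[str, SampleCounts] = {}
    for cond in conds:
        lib = config.library_size[cond]
        mu = config.assigned_fraction * lib * proportions * 2.0 ** log2fc[cond]
        counts = _nb_counts(rng, mu, config.dispersion)
        total = max(lib, int(counts.sum()))
        samples[cond] = SampleCounts(
            condition=cond,
            total_uniquely_mapped=total,
            gene_counts=dict(zip(gene_ids, counts.tolist())),
        )

    gene_truth = pd.DataFrame(
        [
            {
                "gene_id": g,
                "condition": cond,
                "is_de": log2fc[cond][i] != 0.0,
                "true_direction": "up" if log2fc[cond][i] > 0 else (
                    "down" if log2fc[cond][i] < 0 else ""),
                "true_log2fc": log2fc[cond][i],
            }
            for cond in conds if cond != ref
            for g, i in idx.items()
        ]
    )

    # --- splicing events -------------------------------------------------
    se_ids = [f"SE{i:05d}" for i in range(config.n_se_events)]
    ri_ids = [f"RI{i:05d}" for i in range(config.n_ri_events)]
    event_types = {e: SKIPPED_EXON for e in se_ids}
    event_types.update({e: RETAINED_INTRON for e in ri_ids})

    psi0 = rng.uniform(0.2, 0.8, config.n_se_events)
    ret0 = rng.uniform(0.05, 0.4, config.n_ri_events)

    events: dict[str, EventCounts] = {}
    truth_rows = []
    shifts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cond in conds:
        if cond == ref:
            shifts[cond] = (np.zeros(config.n_se_events),
                            np.zeros(config.n_ri_events))
            continue
        frac = config.splice_effect_fraction[cond]
        se_shift = np.zeros(config.n_se_events)
        ri_shift = np.zeros(config.n_ri_events)
        n_se_eff = int(round(frac * config.n_se_events))
        n_ri_eff = int(round(frac * config.n_ri_events))
        if n_se_eff:
            chosen = rng.choice(config.n_se_events, n_se_eff, replace=False)
            se_shift[chosen] = np.where(rng.random(n_se_eff) < 0.5, 1, -1) \
                * config.inclusion_shift
        if n_ri_eff:
            chosen = rng.choice(config.n_ri_events, n_ri_eff, replace=False)
            ri_shift[chosen] = np.where(rng.random(n_ri_eff) < 0.5, 1, -1) \
                * config.inclusion_shift
        shifts[cond] = (se_shift, ri_shift)

    for cond in conds:
        se_shift, ri_shift = shifts[cond]
        psi = _logistic(_logit(psi0) + se_shift)
        ret = _logistic(_logit(ret0) + ri_shift)
        f = config.flanking_fraction
        counts: dict[str, ClassCounts] = {}
        n_reads_se = rng.poisson(config.mean_event_reads, config.n_se_events)
        for i, eid in enumerate(se_ids):
            probs = [(1 - f) * psi[i], (1 - f) * (1 - psi[i]), f]
            incl, skip, flank = rng.multinomial(n_reads_se[i], probs)
            counts[eid] = ClassCounts(int(incl), int(skip), int(flank))
        n_reads_ri = rng.poisson(config.mean_event_reads, config.n_ri_events)
        for i, eid in enumerate(ri_ids):
            incl, flank = rng.multinomial(n_reads_ri[i], [ret[i], 1 - ret[i]])
            counts[eid] = ClassCounts(int(incl), 0, int(flank))
        events[cond] = EventCounts(condition=cond, counts=counts)
        if cond != ref:
            for i, eid in enumerate(se_ids):
                s = se_shift[i]
                truth_rows.append({
                    "event_id": eid, "type": SKIPPED_EXON, "condition": cond,
                    "is_changed": s != 0.0,
                    # lower inclusion -> more skipping
                    "true_direction": "increased_skipping" if s < 0 else (
                        "decreased_skipping" if s > 0 else ""),
                })
            for i, eid in enumerate(ri_ids):
                s = ri_shift[i]
                truth_rows.append({
                    "event_id": eid, "type": RETAINED_INTRON, "condition": cond,
                    "is_changed": s != 0.0,
                    "true_direction": "increased_retention" if s > 0 else (
                        "decreased_retention" if s < 0 else ""),
                })

    return SimulatedExperiment(
        config=config,
        gene_lengths=gene_lengths,
        samples=samples,
        events=events,
        event_types=event_types,
        gene_truth=gene_truth,
        event_truth=pd.DataFrame(truth_rows),
    )


def recovery_report(
    experiment: SimulatedExperiment,
    de_results: Mapping[str, Sequence],
) -> pd.DataFrame:
    """Sensitivity / false-positive rate / direction concordance per condition.

    ``de_results`` maps condition -> DEResult list for that condition
    versus the reference.  Direction concordance is computed over detected
    truly differential genes.
    """
    truth = experiment.gene_truth.set_index(["condition", "gene_id"])
    rows = []
    for cond, results in de_results.items():
        if cond not in experiment.config.conditions:
            raise DataError(f"condition {cond!r} not simulated")
        t = truth.loc[cond]
        unknown = [r.gene_id for r in results if r.gene_id not in t.index]
        if unknown:
            raise DataError(
                f"results contain genes absent from the simulation: "
                f"{unknown[:3]}..."
            )
        detected = {r.gene_id: r for r in results if r.significant}
        true_de = set(t.index[t["is_de"]])
        tested = {r.gene_id for r in results}
        true_null = tested - true_de
        tp = [g for g in detected if g in true_de]
        fp = [g for g in detected if g in true_null]
        concord = [
            detected[g].direction == t.loc[g, "true_direction"] for g in tp
        ]
        rows.append({
            "condition": cond,
            "n_true_de": len(true_de & tested),
            "n_detected": len(detected),
            "sensitivity": len(tp) / len(true_de & tested)
            if true_de & tested else np.nan,
            "false_positive_rate": len(fp) / len(true_null)
            if true_null else np.nan,
            "direction_concordance": float(np.mean(concord))
            if concord else np.nan,
        })
    return pd.DataFrame(rows)
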