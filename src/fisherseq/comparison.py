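"""Condition-similarity inference over significant-set counts.

This layer turns per-comparison result lists into the study-level verdicts:

* *similarity contingency* — are two reference comparisons (e.g. mutant vs
  overexpression and mutant vs knock-down) equally rich in significant
  genes?  A 2x2 Fisher test on significant / non-significant counts.
* *direction contingency* — do two comparisons differ in the balance of
  up- vs down-regulated significant genes?
* *Venn regions* — disjoint membership regions of 2-5 named significant
  sets.
* *gain/loss-of-function verdict* — a mutant-like condition resembles
  overexpression (gain of function) when it shows proportionally fewer
  differentially expressed genes against the overexpression condition than
  against the knock-down, with a significant similarity contingency; and
  symmetrically for loss of function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .errors import DataError
from .stats import fisher_two_sided

__all__ = [
    "ContingencyResult",
    "VennRegions",
    "significant_set",
    "similarity_contingency",
    "direction_contingency",
    "venn_regions",
    "gain_loss_verdict",
    "OVEREXPRESSION_LIKE",
    "KNOCKDOWN_LIKE",
    "INDETERMINATE",
]

OVEREXPRESSION_LIKE = "overexpression_like"
KNOCKDOWN_LIKE = "knockdown_like"
INDETERMINATE = "indeterminate"


@dataclass
class ContingencyResult:
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]
    table: tuple[tuple[int, int], tuple[int, int]]
    p: float  # two-sided Fisher P; NaN when a margin is zero (untestable)

    @property
    def testable(self) -> bool:
        return not math.isnan(self.p)


@dataclass
class VennRegions:
    set_labels: list[str]
    region_counts: dict[frozenset, int] = field(default_factory=dict)
    region_members: dict[frozenset, set] = field(default_factory=dict)


def significant_set(results: Iterable) -> set[str]:
    """Ids (gene or event) whose significance flag is set."""
    out = set()
    for r in results:
        if getattr(r, "significant"):
            out.add(getattr(r, "gene_id", None) or getattr(r, "event_id"))
    return out


def _contingency(
    table, row_labels: tuple[str, str], col_labels: tuple[str, str]
) -> ContingencyResult:
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise DataError("contingency counts must be >= 0")
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    p = math.nan if degenerate else fisher_two_sided([[a, b], [c, d]])
    return ContingencyResult(
        row_labels=row_labels,
        col_labels=col_labels,
        table=((a, b), (c, d)),
        p=p,
    )


def similarity_contingency(
    n_sig_vs_x: int,
    n_nonsig_vs_x: int,
    n_sig_vs_y: int,
    n_nonsig_vs_y: int,
    labels: tuple[str, str] = ("vs_x", "vs_y"),
) -> ContingencyResult:
    """Fisher test on [[sig_x, nonsig_x], [sig_y, nonsig_y]].

    Row denominators may differ between the two comparisons (each
    comparison has its own tested-gene universe).
    """
    return _contingency(
        [[n_sig_vs_x, n_nonsig_vs_x], [n_sig_vs_y, n_nonsig_vs_y]],
        row_labels=labels,
        col_labels=("significant", "non_significant"),
    )


def direction_contingency(
    n_up_x: int,
    n_down_x: int,
    n_up_y: int,
    n_down_y: int,
    labels: tuple[str, str] = ("x", "y"),
) -> ContingencyResult:
    """Fisher test on [[up_x, down_x], [up_y, down_y]]."""
    return _contingency(
        [[n_up_x, n_down_x], [n_up_y, n_down_y]],
        row_labels=labels,
        col_labels=("up", "down"),
    )


def venn_regions(named_sets: Mapping[str, Iterable]) -> VennRegions:
    """Disjoint regions of 2-5 named sets, keyed by the label subset."""
    labels = list(named_sets)
    if not (2 <= len(labels) <= 5):
        raise DataError("venn_regions supports 2 to 5 sets")
    sets = {lab: set(v) for lab, v in named_sets.items()}
    universe = set().union(*sets.values())
    members: dict[frozenset, set] = {}
    for size in range(1, len(labels) + 1):
        for combo in combinations(labels, size):
            members[frozenset(combo)] = set()
    for item in universe:
        key = frozenset(lab for lab in labels if item in sets[lab])
        members[key].add(item)
    return VennRegions(
        set_labels=labels,
        region_counts={k: len(v) for k, v in members.items()},
        region_members=members,
    )


def gain_loss_verdict(
    vs_overexpression: tuple[int, int],
    vs_knockdown: tuple[int, int],
    alpha: float = 0.05,
) -> tuple[str, ContingencyResult]:
    """Classify a mutant-like condition as gain- or loss-of-function-like.

    Each argument is (n_significant, n_non_significant) for the mutant
    compared against that reference condition.  The verdict is
    ``overexpression_like`` when the significant-gene proportion against
    the overexpression reference is smaller than against the knock-down
    reference *and* the similarity contingency rejects at ``alpha``;
    symmetrically ``knockdown_like``; otherwise ``indeterminate``.
    """
    sig_oe, nonsig_oe = vs_overexpression
    sig_kd, nonsig_kd = vs_knockdown
    result = similarity_contingency(
        sig_oe, nonsig_oe, sig_kd, nonsig_kd,
        labels=("vs_overexpression", "vs_knockdown"),
    )
    if not result.testable:
        return INDETERMINATE, result
    prop_oe = sig_oe / (sig_oe + nonsig_oe)
    prop_kd = sig_kd / (sig_kd + nonsig_kd)
    if result.p < alpha and prop_oe < prop_kd:
        return OVEREXPRESSION_LIKE, result
    if result.p < alpha and prop_kd < prop_oe:
        return KNOCKDOWN_LIKE, result
    return INDETERMINATE, result


def contingency_report(results: Sequence[ContingencyResult]) -> list[dict]:
    """JSON-serialisable dump of contingency analyses."""
    return [
        {
            "rows": list(r.row_labels),
            "cols": list(r.col_labels),
            "table": [list(r.table[0]), list(r.table[1])],
            "p": None if math.isnan(r.p) else r.p,
        }
        for r in results
    ]
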