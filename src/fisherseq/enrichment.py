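"""Gene-set over-representation against user-supplied collections.

Given a query gene list, a named collection of gene sets (GMT) and an
explicit background universe, each set is scored with the upper-tail
hypergeometric probability of observing at least the seen overlap — or
with the EASE variant, which removes one gene from the overlap before
taking the tail and is therefore strictly conservative.  Raw P-values are
adjusted across the collection with the Benjamini-Hochberg step-up FDR.

Database content (KEGG, GO, ...) is deliberately not bundled: results
depend on the database version, so sets and background are always inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "overrepresentation_test",
    "bh_fdr",
    "enrich",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with an explicit background universe."""

    sets: dict[str, set] = field(default_factory=dict)
    background: set = field(default_factory=set)

    def __post_init__(self):
        self.background = set(self.background)
        trimmed = {}
        for name, members in self.sets.items():
            kept = set(members) & self.background
            if kept:  # empty-after-intersection sets carry no signal
                trimmed[name] = kept
        self.sets = trimmed


@dataclass
class EnrichmentResult:
    set_name: str
    count: int  # overlap of query and set within background
    set_size: int
    p_raw: float
    p_hypergeom: float
    fdr: float


def overrepresentation_test(
    query: Iterable,
    gene_set: Iterable,
    background: Iterable,
    method: str = "ease",
) -> float:
    """Upper-tail over-representation P-value.

    With ``method="hypergeometric"`` this is P(X >= k) for k observed
    overlaps among |query| draws from a background containing the set;
    ``method="ease"`` scores P(X >= k-1 + 1) after discounting one overlap
    gene (DAVID's conservative convention), returning 1.0 for k <= 1.
    """
    bg = set(background)
    q = set(query) & bg
    if not q:
        raise DataError("query is empty after background intersection")
    s = set(gene_set) & bg
    k = len(q & s)
    N, K, n = len(bg), len(s), len(q)
    if method == "hypergeometric":
        return float(hypergeom.sf(k - 1, N, K, n))
    if method == "ease":
        return float(hypergeom.sf(k - 2, N, K, n)) if k >= 1 else 1.0
    raise DataError(f"unknown method {method!r}")


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted P-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise DataError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich(
    query: Iterable,
    collection: GeneSetCollection,
    method: str = "ease",
) -> list[EnrichmentResult]:
    """Score every set in the collection and rank by raw P.

    Both the chosen method's P and the plain hypergeometric P are reported;
    BH adjustment runs across the collection on the chosen method.
    """
    if not collection.sets:
        raise DataError("empty gene-set collection")
    bg = collection.background
    q = set(query) & bg
    names = sorted(collection.sets)
    p_method = [
        overrepresentation_test(q, collection.sets[n], bg, method=method)
        for n in names
    ]
    p_hyper = [
        overrepresentation_test(q, collection.sets[n], bg, method="hypergeometric")
        for n in names
    ]
    fdrs = bh_fdr(p_method)
    results = [
        EnrichmentResult(
            set_name=n,
            count=len(q & collection.sets[n]),
            set_size=len(collection.sets[n]),
            p_raw=p,
            p_hypergeom=ph,
            fdr=f,
        )
        for n, p, ph, f in zip(names, p_method, p_hyper, fdrs)
    ]
    results.sort(key=lambda r: (r.p_raw, r.set_name))
    return results


def read_gmt(stream: TextIO | Iterable[str]) -> dict[str, set]:
    """Read a GMT file: name <tab> description <tab> member..."""
    sets: dict[str, set] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise DataError(f"GMT record with fewer than 3 fields: {fields[0]!r}")
        sets[fields[0]] = set(f for f in fields[2:] if f)
    return sets


def write_gmt(sets: Mapping[str, Iterable], out: TextIO) -> None:
    for name in sorted(sets):
        members = "\t".join(sorted(sets[name]))
        out.write(f"{name}\tna\t{members}\n")
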