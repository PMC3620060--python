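"""Shared 2x2 contingency statistics.

All pairwise tests in this package are two-sided Fisher's exact tests under
the minimum-likelihood convention: the P-value is the sum of probabilities
of all tables with the same margins whose hypergeometric probability does
not exceed that of the observed table.  A two-proportion normal
approximation is provided as an asymptotic cross-check for large tables
with P-values near 1.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from .errors import DataError

__all__ = [
    "fisher_two_sided",
    "two_proportion_normal_p",
    "bonferroni",
]


def _validate(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise DataError("contingency counts must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        ft = t.astype(float)
        if not np.allclose(ft, np.round(ft)):
            raise DataError("contingency counts must be integers")
        t = np.round(ft).astype(np.int64)
    return t.astype(np.int64)


def fisher_two_sided(table) -> float:
    """Two-sided minimum-likelihood Fisher's exact P for a 2x2 table.

    Degenerate tables (a zero margin) carry no information and return 1.0.
    """
    t = _validate(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


def two_proportion_normal_p(table) -> float:
    """Two-sided pooled two-proportion z-test on the rows of a 2x2 table.

    Asymptotic counterpart of :func:`fisher_two_sided`; used as a
    cross-check for large near-null tables.
    """
    t = _validate(table).astype(float)
    n1, n2 = t[0].sum(), t[1].sum()
    if n1 == 0 or n2 == 0:
        return 1.0
    p1, p2 = t[0, 0] / n1, t[1, 0] / n2
    pooled = (t[0, 0] + t[1, 0]) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0:
        return 1.0
    z = (p1 - p2) / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted P-value: min(1, p * m)."""
    if m < 1:
        raise DataError("Bonferroni m must be >= 1")
    return min(1.0, p_raw * m)
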