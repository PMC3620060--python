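"""Validation arithmetic for qPCR and semi-quantitative splicing PCR.

Relative quantification follows the Livak ddCt convention: per condition,
dCt = mean Ct(target) - mean Ct(normalizer); ddCt = dCt(condition) -
dCt(reference); relative expression = 2^(-ddCt), so one cycle earlier
means a doubling.  The sign convention is configurable because some
reports use the positive exponent.

Semi-quantitative splicing validation takes per-replicate band
intensities, forms an unspliced:spliced ratio per replicate, averages per
condition and reports log2 of the ratio relative to the reference
condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import DataError

__all__ = ["CtMeasurement", "BandQuantification", "delta_delta_ct",
           "splice_ratio_fc"]


@dataclass
class CtMeasurement:
    """Threshold-cycle replicates for one gene in one condition."""

    condition: str
    gene: str
    ct_values: list[float]

    def __post_init__(self):
        if not self.ct_values:
            raise DataError(
                f"{self.gene}/{self.condition}: at least one Ct replicate required")
        if any(ct <= 0 for ct in self.ct_values):
            raise DataError(f"{self.gene}/{self.condition}: Ct values must be > 0")

    @property
    def mean_ct(self) -> float:
        return sum(self.ct_values) / len(self.ct_values)


@dataclass
class BandQuantification:
    """Per-replicate (unspliced, spliced) band intensities for one condition."""

    condition: str
    unspliced_intensity: list[float]
    spliced_intensity: list[float]

    def __post_init__(self):
        if len(self.unspliced_intensity) != len(self.spliced_intensity):
            raise DataError(
                f"{self.condition}: unspliced/spliced replicate counts differ")
        if any(v < 0 for v in self.unspliced_intensity + self.spliced_intensity):
            raise DataError(f"{self.condition}: intensities must be >= 0")


def _as_ct_map(measurements, role: str) -> Mapping[str, CtMeasurement]:
    if isinstance(measurements, Mapping):
        return measurements
    out = {}
    for m in measurements:
        if m.condition in out:
            raise DataError(f"duplicate {role} measurement for {m.condition}")
        out[m.condition] = m
    return out


def delta_delta_ct(
    target: Mapping[str, CtMeasurement] | Sequence[CtMeasurement],
    normalizer: Mapping[str, CtMeasurement] | Sequence[CtMeasurement],
    reference_condition: str,
    positive_exponent: bool = False,
) -> pd.DataFrame:
    """ddCt relative quantification per condition.

    Returns a tidy frame with delta_ct, delta_delta_ct, relative_expression
    and log2fc; the reference condition maps to fold 1.0 exactly.  With
    ``positive_exponent`` the sign-flipped 2^(+ddCt) convention is used instead
    of Livak's 2^(-ddCt).
    """
    tgt = _as_ct_map(target, "target")
    nrm = _as_ct_map(normalizer, "normalizer")
    if reference_condition not in tgt or reference_condition not in nrm:
        raise DataError(
            f"reference condition {reference_condition!r} missing from input")
    missing = set(tgt) - set(nrm)
    if missing:
        raise DataError(f"no normalizer measurement for: {sorted(missing)}")

    dct = {c: tgt[c].mean_ct - nrm[c].mean_ct for c in tgt}
    ref_dct = dct[reference_condition]
    sign = 1.0 if positive_exponent else -1.0
    rows = []
    for cond in tgt:
        ddct = dct[cond] - ref_dct
        log2fc = sign * ddct
        rows.append({
            "condition": cond,
            "gene": tgt[cond].gene,
            "delta_ct": dct[cond],
            "delta_delta_ct": ddct,
            "relative_expression": 2.0 ** log2fc,
            "log2fc": log2fc,
        })
    df = pd.DataFrame(rows)
    df.attrs["convention"] = (
        "2^(+ddCt)" if positive_exponent else "2^(-ddCt) (Livak)")
    return df


def splice_ratio_fc(
    bands: Mapping[str, BandQuantification] | Sequence[BandQuantification],
    reference_condition: str,
) -> pd.DataFrame:
    """log2 change in the unspliced:spliced band ratio versus a reference.

    Replicates with zero spliced intensity are dropped with a warning
    (their ratio is undefined).
    """
    if not isinstance(bands, Mapping):
        bands = {b.condition: b for b in bands}
    if reference_condition not in bands:
        raise DataError(
            f"reference condition {reference_condition!r} missing from input")

    def mean_ratio(b: BandQuantification) -> float:
        ratios = []
        for u, s in zip(b.unspliced_intensity, b.spliced_intensity):
            if s == 0:
                warnings.warn(
                    f"{b.condition}: replicate with zero spliced intensity "
                    "dropped", stacklevel=2)
                continue
            ratios.append(u / s)
        if not ratios:
            raise DataError(f"{b.condition}: no usable replicates")
        return sum(ratios) / len(ratios)

    ref_ratio = mean_ratio(bands[reference_condition])
    rows = []
    for cond, b in bands.items():
        r = mean_ratio(b)
        rows.append({
            "condition": cond,
            "unspliced_spliced_ratio": r,
            "log2fc_vs_reference": math.log2(r / ref_ratio),
        })
    return pd.DataFrame(rows)
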