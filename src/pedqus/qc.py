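"""Cohort exclusion filters and robust outlier handling.

Two quality-control steps precede any modelling of the sonography outcomes:

1. :func:`apply_exclusions` removes children whose liver enzymes are elevated
   or whose BMI standard-deviation score marks them as under-/overweight
   (|BMI SDS| > 1.96), returning an audit of who was dropped and why.
2. :func:`semi_winsorize` replaces outlying measurements by the nearest
   robust bound (median ± k · scaled MAD) instead of discarding them, so the
   sample size is preserved while extreme values cannot dominate
   correlations or curve fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BMI_SDS_LIMIT",
    "MAD_NORMAL_CONSTANT",
    "ExclusionAudit",
    "WinsorizeResult",
    "apply_exclusions",
    "scaled_mad",
    "semi_winsorize",
]

#: |BMI SDS| beyond this marks under-/overweight (two-sided 95% band).
BMI_SDS_LIMIT = 1.96

#: Consistency factor making the MAD estimate the SD of a normal sample.
MAD_NORMAL_CONSTANT = 1.4826


@dataclass(frozen=True)
class ExclusionAudit:
    """Bookkeeping for the cohort exclusion step."""

    n_input: int
    n_enzyme_excluded: int
    n_bmi_excluded: int
    n_retained: int
    excluded_ids: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_enzyme_excluded": self.n_enzyme_excluded,
            "n_bmi_excluded": self.n_bmi_excluded,
            "n_retained": self.n_retained,
            "excluded": [
                {"id": rid, "reasons": list(reasons)}
                for rid, reasons in self.excluded_ids
            ],
        }


@dataclass(frozen=True)
class WinsorizeResult:
    """Cleaned series plus the audit trail of the semi-winsorization."""

    values: np.ndarray
    lower_bound: float
    upper_bound: float
    n_replaced: int
    replaced_indices: np.ndarray
    k: float
    mad_scaled: float
    median: float

    @property
    def replaced_fraction(self) -> float:
        n_obs = int(np.sum(np.isfinite(self.values)))
        return self.n_replaced / n_obs if n_obs else 0.0


def apply_exclusions(
    records: pd.DataFrame,
    *,
    bmi_limit: float = BMI_SDS_LIMIT,
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Drop children with elevated liver enzymes or |BMI SDS| > `bmi_limit`.

    Both criteria are evaluated independently; a record may carry both
    reasons.  For the audit's marginal counts a record is tallied under the
    enzyme reason first, so the counts add up when the reasons are disjoint
    (as in the packaged recruitment fixture: 129 = 112 + 8 + 9).

    Parameters
    ----------
    records
        Cohort table with at least ``id``, ``bmi_sds`` and
        ``enzymes_elevated`` columns.
    bmi_limit
        Two-sided BMI SDS cut-off.

    Returns
    -------
    (retained, audit)
        Retained rows (original order, original index) and the
        :class:`ExclusionAudit`.
    """
    for col in ("bmi_sds", "enzymes_elevated"):
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")
    bmi = pd.to_numeric(records["bmi_sds"], errors="coerce")
    if bmi.isna().any():
        bad = records.loc[bmi.isna(), "id"].tolist() if "id" in records else list(
            records.index[bmi.isna()]
        )
        raise ValueError(f"missing or non-numeric bmi_sds for record(s): {bad}")

    enzyme = records["enzymes_elevated"].astype(bool).to_numpy()
    bmi_extreme = (bmi.abs() > bmi_limit).to_numpy()
    excluded = enzyme | bmi_extreme
    retained = records.loc[~excluded]

    ids = (
        records["id"].astype(str)
        if "id" in records.columns
        else records.index.astype(str)
    )
    excluded_ids: list[tuple[str, tuple[str, ...]]] = []
    for i in np.flatnonzero(excluded):
        reasons = []
        if enzyme[i]:
            reasons.append("elevated_enzymes")
        if bmi_extreme[i]:
            reasons.append("bmi_sds_out_of_range")
        excluded_ids.append((ids.iloc[i], tuple(reasons)))

    audit = ExclusionAudit(
        n_input=len(records),
        n_enzyme_excluded=int(enzyme.sum()),
        n_bmi_excluded=int((bmi_extreme & ~enzyme).sum()),
        n_retained=int((~excluded).sum()),
        excluded_ids=excluded_ids,
    )
    return retained, audit


def scaled_mad(values, *, constant: float = MAD_NORMAL_CONSTANT) -> float:
    """Median absolute deviation scaled for normal consistency.

    Returns ``constant * median(|x - median(x)|)`` over the finite entries.
    With the default constant 1.4826 the statistic estimates the standard
    deviation of a Gaussian sample.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("scaled_mad requires at least one finite value")
    med = np.median(x)
    return float(constant * np.median(np.abs(x - med)))


def semi_winsorize(
    values,
    k: float = 2.5,
    *,
    mad_constant: float = MAD_NORMAL_CONSTANT,
) -> WinsorizeResult:
    """Replace outliers beyond median ± k·MAD by the nearest bound.

    Values outside ``[median - k*mad, median + k*mad]`` (MAD scaled by
    `mad_constant`) are set to the bound they exceed; everything else is
    returned untouched.  Missing (NaN) entries pass through unchanged and do
    not count as replacements.  If the MAD is zero on non-constant data no
    replacement is performed and a warning is emitted, since the bounds
    would degenerate to the median.

    Parameters
    ----------
    values
        Numeric sequence (NaN allowed).
    k
        Bound multiplier, > 0.  The conventional outlier rule uses 2.5.
    mad_constant
        MAD scaling; set to 1.0 for the raw (unscaled) MAD rule.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    x = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("semi_winsorize requires at least two finite values")

    med = float(np.median(x[finite]))
    mad = scaled_mad(x[finite], constant=mad_constant)
    lower, upper = med - k * mad, med + k * mad

    if mad == 0.0:
        if np.unique(x[finite]).size > 1:
            warnings.warn(
                "MAD is zero on non-constant data; semi-winsorization skipped",
                RuntimeWarning,
                stacklevel=2,
            )
        replaced = np.zeros(0, dtype=int)
        return WinsorizeResult(
            values=x, lower_bound=med, upper_bound=med, n_replaced=0,
            replaced_indices=replaced, k=k, mad_scaled=mad, median=med,
        )

    out_low = finite & (x < lower)
    out_high = finite & (x > upper)
    x[out_low] = lower
    x[out_high] = upper
    replaced = np.flatnonzero(out_low | out_high)
    return WinsorizeResult(
        values=x,
        lower_bound=lower,
        upper_bound=upper,
        n_replaced=int(replaced.size),
        replaced_indices=replaced,
        k=k,
        mad_scaled=mad,
        median=med,
    )
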