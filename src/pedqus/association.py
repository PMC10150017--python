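"""Bivariate correlation battery and power/sensitivity calculations.

Implements the three correlation measures used when screening quantitative
ultrasound outcomes against cohort covariates — Pearson's r for pairs of
continuous variables, the point-biserial r for binary/continuous pairs, and
Kendall's tau-b (tie-corrected) where a variable is coarsely recorded — plus
the Fisher-z minimum detectable correlation used to qualify null findings.

Missing data are handled by pairwise deletion, so each pair reports its own
n.  No multiple-testing correction is applied; the battery is exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "CorrelationMatrix",
    "pearson",
    "point_biserial",
    "kendall_tau_b",
    "min_detectable_r",
    "correlation_matrix",
]


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    n: int
    df: int
    p: float

    def __post_init__(self):
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric matrix of pairwise correlation results."""

    variables: list[str]
    results: dict[tuple[str, str], CorrelationResult]
    methods: dict[tuple[str, str], str]

    def get(self, a: str, b: str) -> CorrelationResult:
        key = (a, b) if (a, b) in self.results else (b, a)
        return self.results[key]

    def r_frame(self) -> pd.DataFrame:
        k = len(self.variables)
        mat = np.eye(k)
        for i, a in enumerate(self.variables):
            for j, b in enumerate(self.variables):
                if i < j:
                    mat[i, j] = mat[j, i] = self.get(a, b).r
        return pd.DataFrame(mat, index=self.variables, columns=self.variables)

    def to_records(self) -> list[dict]:
        out = []
        for (a, b), res in self.results.items():
            out.append(
                {"var_a": a, "var_b": b, "method": res.method, "r": res.r,
                 "n": res.n, "df": res.df, "p": res.p}
            )
        return out


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation; p from the t transform with n-2 df."""
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"pearson requires >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    res = stats.pearsonr(x, y)
    return CorrelationResult("pearson", float(res.statistic), n, n - 2,
                             float(res.pvalue))


def point_biserial(x, y) -> CorrelationResult:
    """Correlation between a binary and a continuous variable.

    Equals the Pearson correlation on the 0/1-coded binary; the sign follows
    the supplied coding (recoding x as 1-x flips it).
    """
    x, y = _paired(x, y)
    levels = np.unique(x)
    if levels.size != 2:
        raise ValueError(
            f"point_biserial requires a binary x with both levels; got {levels}"
        )
    coded = (x == levels[1]).astype(float)
    res = stats.pearsonr(coded, y)
    n = x.size
    return CorrelationResult("point_biserial", float(res.statistic), n, n - 2,
                             float(res.pvalue))


def kendall_tau_b(x, y) -> CorrelationResult:
    """Kendall's tau-b with tie correction.

    The p-value uses exact enumeration for n <= 8 without ties and the
    tie-adjusted normal approximation otherwise.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"kendall_tau_b requires >= 3 complete pairs, got {n}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined: a variable is all-tied")
    has_ties = np.unique(x).size < n or np.unique(y).size < n
    method = "exact" if (n <= 8 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return CorrelationResult("kendall_tau_b", float(res.statistic), n, n - 2,
                             float(res.pvalue))


def min_detectable_r(n: int, power: float = 0.80, alpha: float = 0.05) -> float:
    """Smallest correlation detectable with the given power at sample size n.

    Uses the Fisher-z approximation for the two-sided test of rho = 0:
    ``r = tanh[(z_{1-alpha/2} + z_power) / sqrt(n - 3)]``.
    """
    if n <= 3:
        raise ValueError(f"min_detectable_r requires n >= 4, got {n}")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    z = (stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)) / np.sqrt(n - 3)
    return float(np.tanh(z))


_METHODS = {
    "pearson": pearson,
    "point_biserial": point_biserial,
    "kendall_tau_b": kendall_tau_b,
}

#: Cohort fields that are binary and enter as point-biserial correlations,
#: with their 0/1 coding (reference level listed first).
BINARY_CODINGS = {
    "sex": ("male", "female"),
    "cooperation": ("calm", "restless"),
    "enzymes_elevated": (False, True),
}


def _coded_column(records: pd.DataFrame, name: str) -> np.ndarray:
    col = records[name]
    if name in BINARY_CODINGS:
        zero, one = BINARY_CODINGS[name]
        return np.where(col.isna(), np.nan, (col == one).astype(float))
    return pd.to_numeric(col, errors="raise").to_numpy(dtype=float)


def correlation_matrix(
    records: pd.DataFrame,
    variables: list[str],
    method_map: dict[tuple[str, str], str] | None = None,
) -> CorrelationMatrix:
    """Assemble the full symmetric correlation matrix over `variables`.

    Method choice per pair: an explicit `method_map` entry wins; otherwise
    pairs involving a binary field use the point-biserial correlation, pairs
    involving abdominal wall thickness use Kendall's tau-b, and all other
    pairs use Pearson's r.  Missing values are deleted pairwise.
    """
    for v in variables:
        if v not in records.columns:
            raise ValueError(f"unknown field {v!r} in variable list")
    method_map = dict(method_map or {})
    results: dict[tuple[str, str], CorrelationResult] = {}
    chosen: dict[tuple[str, str], str] = {}
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            method = method_map.get((a, b)) or method_map.get((b, a))
            if method is None:
                if a in BINARY_CODINGS or b in BINARY_CODINGS:
                    method = "point_biserial"
                elif "wall_mm" in (a, b):
                    method = "kendall_tau_b"
                else:
                    method = "pearson"
            xa, xb = _coded_column(records, a), _coded_column(records, b)
            if method == "point_biserial":
                # put the binary variable first
                if a in BINARY_CODINGS:
                    res = _METHODS[method](xa, xb)
                else:
                    res = _METHODS[method](xb, xa)
            else:
                res = _METHODS[method](xa, xb)
            results[(a, b)] = res
            chosen[(a, b)] = method
    return CorrelationMatrix(list(variables), results, chosen)
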