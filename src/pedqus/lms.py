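"""LMS (Box-Cox Cole-Green) reference-centile estimation.

The LMS method models a positive-valued measurement ``y`` whose distribution
shifts with a covariate ``x`` (age, BMI SDS, wall thickness, ...) through
three smooth curves:

* ``L(x)`` — the Box-Cox power that symmetrizes the distribution (skewness),
* ``M(x)`` — the median,
* ``S(x)`` — the coefficient of variation.

Conditional on ``x``, the transformed value

    z = [ (y/M)^L - 1 ] / (L * S)        (L != 0)
    z = ln(y/M) / S                      (L == 0)

is standard normal, so any centile curve is ``M (1 + L S z_alpha)^{1/L}``
and any new measurement converts to a z-score against the chart.

Each of the three curves is a penalized cubic B-spline (P-spline, second
order difference penalty) on its link scale — identity for L and M, log for
S (keeping the coefficient of variation positive; the median's positivity
is enforced during fitting).  The requested degrees of freedom fix the
roughness penalty: ``df = 0`` is a constant, ``df = 1`` a straight line, and
``df >= 2`` a smooth curve whose smoother trace equals ``df + 1``.  Fitting
maximizes the penalized Box-Cox Cole-Green likelihood by cyclic penalized
Fisher scoring of the three curves; smoothness is chosen by BIC grid search
over df triples and verified by k-fold cross-validated held-out likelihood.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import solve
from scipy.optimize import brentq

__all__ = [
    "DEFAULT_CENTILES",
    "LMS",
    "LMSResults",
    "ParamCurve",
    "PercentileTable",
    "bccg_loglik",
    "boxcox_z",
    "centile",
    "cross_validate_lms",
    "df_grid_search",
    "fit_lms",
    "reference_table",
    "zscore_of",
]

#: Default chart centile levels (probabilities).
DEFAULT_CENTILES = (0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97)

_L_EPS = 1e-4  # |L| below this uses the log (L == 0) branch
_S_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# BCCG distribution primitives
# ---------------------------------------------------------------------------

def boxcox_z(y, L, M, S):
    """Box-Cox z-score of measurement `y` under parameters L, M, S.

    Vectorized over any broadcastable combination of arguments.
    """
    y, L, M, S = np.broadcast_arrays(
        *[np.asarray(a, dtype=float) for a in (y, L, M, S)]
    )
    if np.any(y <= 0):
        raise ValueError(f"y must be > 0 (offending index {int(np.argmax(y <= 0))})")
    if np.any(M <= 0):
        raise ValueError(f"M must be > 0 (offending index {int(np.argmax(M <= 0))})")
    if np.any(S <= 0):
        raise ValueError(f"S must be > 0 (offending index {int(np.argmax(S <= 0))})")
    s = np.log(y / M)
    small = np.abs(L) < _L_EPS
    Lsafe = np.where(small, 1.0, L)
    z = np.where(small, s / S, (np.exp(Lsafe * s) - 1.0) / (Lsafe * S))
    return z if z.ndim else float(z)


def centile(alpha, L, M, S):
    """Measurement value at probability `alpha`; inverse of :func:`boxcox_z`."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha <= 0) | (alpha >= 1)):
        raise ValueError("alpha must lie strictly in (0, 1)")
    z = stats.norm.ppf(alpha)
    z, L, M, S = np.broadcast_arrays(
        z, *[np.asarray(a, dtype=float) for a in (L, M, S)]
    )
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be > 0")
    small = np.abs(L) < _L_EPS
    base = 1.0 + L * S * z
    if np.any(~small & (base <= 0)):
        bad = np.asarray(alpha)[np.unravel_index(
            int(np.argmax(~small & (base <= 0))), base.shape)] \
            if np.asarray(alpha).shape == base.shape else alpha
        raise ValueError(
            f"centile undefined: 1 + L*S*z <= 0 for alpha={bad} (skew too strong)"
        )
    Lsafe = np.where(small, 1.0, L)
    y = np.where(small, M * np.exp(S * z), M * np.abs(base) ** (1.0 / Lsafe))
    return y if y.ndim else float(y)


def _bccg_loglik_terms(y, L, M, S):
    z = boxcox_z(y, L, M, S)
    z = np.asarray(z, dtype=float)
    return (
        -0.5 * math.log(2 * math.pi)
        - 0.5 * z**2
        - np.log(S * y)
        + L * np.log(y / M)
    )


def bccg_loglik(y, L, M, S) -> float:
    """Total Box-Cox Cole-Green log-likelihood of `y` under pointwise L, M, S.

    Per observation this is the normal log-density of the Box-Cox z-score
    plus the Jacobian of the transformation:
    ``log phi(z) - log(S*y) + L*log(y/M)``.
    """
    terms = _bccg_loglik_terms(y, L, M, S)
    if not np.all(np.isfinite(terms)):
        raise ValueError(
            f"non-finite log-likelihood at index {int(np.argmax(~np.isfinite(terms)))}"
        )
    return float(np.sum(terms))


def bccg_pdf(y, L, M, S):
    """BCCG density (untruncated form; integrates to ~1 for moderate skew)."""
    return np.exp(_bccg_loglik_terms(y, L, M, S))


def _fast_terms(y, logy, L, M, S):
    # unvalidated vectorized log-likelihood terms (fitting hot path);
    # caller guarantees y > 0, M > 0, S > 0
    s = logy - np.log(M)
    small = np.abs(L) < _L_EPS
    Lsafe = np.where(small, 1.0, L)
    z = np.where(small, s / S, (np.exp(Lsafe * s) - 1.0) / (Lsafe * S))
    return -_HALF_LOG_2PI - 0.5 * z * z - np.log(S) - logy + L * s


_HALF_LOG_2PI = 0.5 * math.log(2 * math.pi)


# ---------------------------------------------------------------------------
# Parameter curves
# ---------------------------------------------------------------------------

@dataclass
class ParamCurve:
    """One fitted parameter curve (L, M or S) on its link scale.

    ``kind`` is 'constant' (df 0), 'linear' (df 1) or 'pspline' (df >= 2,
    cubic B-spline with second-order difference penalty whose smoother trace
    matches df + 1).
    """

    kind: str
    link: str            # 'identity' | 'log'
    df: int              # requested df (0 constant, 1 linear, >=2 smooth)
    coef: np.ndarray
    x_min: float
    x_max: float
    x_center: float = 0.0          # linear: centering constant
    knots: np.ndarray | None = None  # pspline: full knot vector (degree 3)
    lam: float = 0.0
    edf: float = 1.0

    def eta(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.x_min, self.x_max)
        if self.kind == "constant":
            return np.full(x.shape, self.coef[0])
        if self.kind == "linear":
            return self.coef[0] + self.coef[1] * (x - self.x_center)
        return BSpline(self.knots, self.coef, 3)(x)

    def value(self, x):
        eta = self.eta(x)
        return np.exp(eta) if self.link == "log" else eta

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "link": self.link,
            "df": self.df,
            "coef": np.asarray(self.coef).tolist(),
            "x_min": self.x_min,
            "x_max": self.x_max,
            "x_center": self.x_center,
            "knots": None if self.knots is None else np.asarray(self.knots).tolist(),
            "lam": self.lam,
            "edf": self.edf,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamCurve":
        d = dict(d)
        d["coef"] = np.asarray(d["coef"], dtype=float)
        if d.get("knots") is not None:
            d["knots"] = np.asarray(d["knots"], dtype=float)
        return cls(**d)


class _CurveFitter:
    """Design matrix, penalty and Fisher-scoring update for one curve."""

    def __init__(self, x, df, link, n_basis=10):
        self.link = link
        self.df = int(df)
        self.x_min, self.x_max = float(np.min(x)), float(np.max(x))
        self.x_center = float(np.mean(x))
        self.lam = 1.0
        self.knots = None
        if self.df == 0:
            self.B = np.ones((x.size, 1))
            self.P = None
        elif self.df == 1:
            self.B = np.column_stack([np.ones_like(x), x - self.x_center])
            self.P = None
        else:
            m = max(n_basis, self.df + 4)
            inner = np.linspace(self.x_min, self.x_max, m - 2)
            self.knots = np.r_[[self.x_min] * 3, inner, [self.x_max] * 3]
            xx = np.clip(x, self.x_min, self.x_max)
            self.B = BSpline.design_matrix(xx, self.knots, 3).toarray()
            D = np.diff(np.eye(m), n=2, axis=0)
            self.P = D.T @ D

    def init_coef(self, const_eta: float) -> np.ndarray:
        if self.df == 0:
            return np.array([const_eta])
        if self.df == 1:
            return np.array([const_eta, 0.0])
        # B-splines form a partition of unity: constant coefficients give a
        # constant curve
        return np.full(self.B.shape[1], const_eta)

    def _penalty_spectrum(self, w) -> np.ndarray:
        """Demmler-Reinsch eigenvalues: trace(lam) = sum 1/(1 + lam*d)."""
        A = self.B.T @ (w[:, None] * self.B)
        A = A + 1e-10 * np.eye(A.shape[0]) * max(1.0, np.trace(A))
        R = np.linalg.cholesky(A)
        Rinv = np.linalg.inv(R)
        M = Rinv @ self.P @ Rinv.T
        return np.clip(np.linalg.eigvalsh(0.5 * (M + M.T)), 0.0, None)

    def calibrate_lambda(self, w) -> None:
        """Pick the penalty so the smoother trace matches df + 1."""
        if self.P is None:
            return
        target = self.df + 1.0
        d = self._penalty_spectrum(w)

        def f(loglam):
            return float(np.sum(1.0 / (1.0 + 10.0**loglam * d))) - target

        lo, hi = -8.0, 12.0
        if f(lo) <= 0:     # even tiny penalty gives too few df (shouldn't happen)
            self.lam = 10.0**lo
        elif f(hi) >= 0:   # huge penalty still above target: use hi
            self.lam = 10.0**hi
        else:
            self.lam = 10.0 ** brentq(f, lo, hi, xtol=1e-10)

    def newton_step(self, coef, u, w):
        """Penalized Fisher-scoring direction for the coefficient vector."""
        B = self.B
        A = B.T @ (w[:, None] * B)
        g = B.T @ u
        if self.P is not None:
            A = A + self.lam * self.P
            g = g - self.lam * (self.P @ coef)
        A = A + 1e-10 * np.eye(A.shape[0]) * max(1.0, np.trace(A))
        return solve(A, g, assume_a="pos")

    def edf(self, w) -> float:
        if self.df == 0:
            return 1.0
        if self.df == 1:
            return 2.0
        d = self._penalty_spectrum(w)
        return float(np.sum(1.0 / (1.0 + self.lam * d)))

    def penalty(self, coef) -> float:
        if self.P is None:
            return 0.0
        return 0.5 * self.lam * float(coef @ self.P @ coef)

    def make_curve(self, coef, w) -> ParamCurve:
        kind = "constant" if self.df == 0 else ("linear" if self.df == 1 else "pspline")
        return ParamCurve(
            kind=kind, link=self.link, df=self.df, coef=np.asarray(coef, float),
            x_min=self.x_min, x_max=self.x_max, x_center=self.x_center,
            knots=self.knots, lam=self.lam if self.P is not None else 0.0,
            edf=self.edf(w),
        )


# ---------------------------------------------------------------------------
# Score functions (derivatives of the BCCG log-likelihood w.r.t. predictors)
# ---------------------------------------------------------------------------

def _score_M(y, L, M, S, z):
    # d loglik / d M (identity link, as in the Cole-Green convention)
    u = (z / S + L * (z**2 - 1.0)) / M
    w = (1.0 / S**2 + 2.0 * L**2) / M**2  # expected information
    return u, w


def _score_S(y, L, M, S, z):
    # d loglik / d eta_S with log link
    u = z**2 - 1.0
    w = np.full_like(u, 2.0)
    return u, w


def _score_L(y, L, M, S, z):
    # d loglik / d L (identity link); curvature from central differences
    s = np.log(y / M)
    small = np.abs(L) < _L_EPS
    Lsafe = np.where(small, 1.0, L)
    dz = np.where(
        small,
        s**2 / (2.0 * S),
        s * (1.0 + Lsafe * S * z) / (Lsafe * S) - z / Lsafe,
    )
    u = s - z * dz
    h = 1e-3
    llp = _bccg_loglik_terms(y, L + h, M, S)
    llm = _bccg_loglik_terms(y, L - h, M, S)
    ll0 = _bccg_loglik_terms(y, L, M, S)
    w = -(llp - 2.0 * ll0 + llm) / h**2
    w = np.clip(w, 1e-4, None)
    return u, w


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PercentileTable:
    """Reference values on a covariate grid x centile levels."""

    covariate: str
    grid: np.ndarray
    levels: tuple[float, ...]
    values: pd.DataFrame  # index = grid, columns = levels
    stratum: str | None = None

    def to_csv(self, path) -> None:
        self.values.to_csv(path)


class LMS:
    """LMS (Box-Cox Cole-Green) centile model for one outcome vs one covariate.

    Parameters
    ----------
    x, y
        Covariate and (strictly positive) outcome, paired; NaN pairs dropped.
    dfs
        Requested degrees of freedom ``(df_L, df_M, df_S)``, each in
        {0, ..., 5}: 0 = constant, 1 = linear, >= 2 = penalized spline with
        smoother trace df + 1.
    xname, yname, stratum
        Labels carried into results and charts.
    """

    MAX_DF = 5

    def __init__(self, x, y, dfs=(0, 2, 0), *, xname="x", yname="y",
                 stratum=None, n_basis=10):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if x.size < 20:
            raise ValueError(f"LMS requires n >= 20 observations, got {x.size}")
        if np.any(y <= 0):
            raise ValueError("all y must be strictly positive")
        dfs = tuple(int(d) for d in dfs)
        if len(dfs) != 3 or any(d < 0 or d > self.MAX_DF for d in dfs):
            raise ValueError(f"dfs must be three values in 0..{self.MAX_DF}, got {dfs}")
        if np.ptp(x) == 0 and any(d > 0 for d in dfs):
            raise ValueError("covariate is constant; only dfs=(0,0,0) is fittable")
        self.x, self.y = x, y
        self.dfs = dfs
        self.xname, self.yname, self.stratum = xname, yname, stratum
        self.n_basis = n_basis

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, covariate: str,
                       dfs=(0, 2, 0), **kw) -> "LMS":
        return cls(df[covariate].to_numpy(float), df[outcome].to_numpy(float),
                   dfs, xname=covariate, yname=outcome, **kw)

    # -- fitting -----------------------------------------------------------

    def fit(self, maxiter: int = 200, tol: float = 5e-7) -> "LMSResults":
        """Maximize the penalized BCCG likelihood by cyclic Fisher scoring."""
        x, y = self.x, self.y
        df_L, df_M, df_S = self.dfs

        fitters = {
            "M": _CurveFitter(x, df_M, "identity", self.n_basis),
            "S": _CurveFitter(x, df_S, "log", self.n_basis),
            "L": _CurveFitter(x, df_L, "identity", self.n_basis),
        }
        med = float(np.median(y))
        mad = float(np.median(np.abs(y - med))) * 1.4826
        s0 = min(max(mad / med, 1e-3), 2.0)
        coefs = {
            "M": fitters["M"].init_coef(med),
            "S": fitters["S"].init_coef(math.log(s0)),
            "L": fitters["L"].init_coef(1.0),
        }
        scores = {"M": _score_M, "S": _score_S, "L": _score_L}
        logy = np.log(y)

        def curve_values(name, coef):
            eta = fitters[name].B @ coef
            if name == "S":
                return np.exp(np.clip(eta, math.log(_S_FLOOR), 20.0))
            if name == "L":
                return np.clip(eta, -4.0, 4.0)
            return eta  # M, identity link; positivity guarded below

        vals = {n: curve_values(n, coefs[n]) for n in fitters}
        pens = {n: fitters[n].penalty(coefs[n]) for n in fitters}

        def pen_loglik():
            if np.any(vals["M"] <= 0):
                return -np.inf
            ll = float(np.sum(_fast_terms(y, logy, vals["L"], vals["M"],
                                          vals["S"])))
            return ll - sum(pens.values())

        converged = False
        prev = pen_loglik()
        weights = {}
        for _ in range(maxiter):
            for name in ("M", "S", "L"):
                L, M, S = vals["L"], vals["M"], vals["S"]
                z = np.asarray(boxcox_z(y, L, M, S))
                u, w = scores[name](y, L, M, S, z)
                w = np.clip(w, 1e-8, None)
                weights[name] = w
                fitters[name].calibrate_lambda(w)
                step = fitters[name].newton_step(coefs[name], u, w)
                base, base_val, base_pen = coefs[name], vals[name], pens[name]
                cur = pen_loglik()
                frac, improved = 1.0, False
                for _ in range(6):
                    cand = base + frac * step
                    vals[name] = curve_values(name, cand)
                    pens[name] = fitters[name].penalty(cand)
                    if pen_loglik() > cur - 1e-12:
                        coefs[name] = cand
                        improved = True
                        break
                    frac *= 0.5
                if not improved:
                    vals[name], pens[name] = base_val, base_pen
            now = pen_loglik()
            if abs(now - prev) < tol:
                converged = True
                break
            prev = now

        if not converged:
            warnings.warn(
                f"LMS fit for {self.yname} did not converge in {maxiter} cycles",
                RuntimeWarning, stacklevel=2,
            )
        curves = {
            n: fitters[n].make_curve(coefs[n], weights.get(n, np.ones_like(y)))
            for n in fitters
        }
        L, M, S = (curves[n].value(x) for n in ("L", "M", "S"))
        loglik = float(np.sum(_bccg_loglik_terms(y, L, M, S)))
        edf_total = sum(c.edf for c in curves.values())
        bic = -2.0 * loglik + math.log(x.size) * edf_total
        return LMSResults(
            model=self, curves=curves, loglik=loglik, edf_total=edf_total,
            bic=bic, converged=converged,
        )


@dataclass
class LMSResults:
    """Fitted L/M/S curves plus likelihood-based fit metadata."""

    model: LMS
    curves: dict[str, ParamCurve]
    loglik: float
    edf_total: float
    bic: float
    converged: bool

    # -- curve access ------------------------------------------------------

    @property
    def n(self) -> int:
        return self.model.x.size

    @property
    def x_range(self) -> tuple[float, float]:
        c = self.curves["M"]
        return (c.x_min, c.x_max)

    def L(self, x):
        return self.curves["L"].value(x)

    def M(self, x):
        return self.curves["M"].value(x)

    def S(self, x):
        return self.curves["S"].value(x)

    def _check_range(self, x, allow_extrapolate):
        x = np.asarray(x, dtype=float)
        lo, hi = self.x_range
        if not allow_extrapolate and (np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9)):
            bad = x[(x < lo - 1e-9) | (x > hi + 1e-9)]
            raise ValueError(
                f"covariate value(s) {bad} outside fitted range [{lo:g}, {hi:g}]; "
                "pass allow_extrapolate=True to override"
            )

    # -- chart operations --------------------------------------------------

    def zscore(self, x, y, *, allow_extrapolate: bool = False):
        """z-score of measurement `y` taken at covariate value `x`."""
        self._check_range(x, allow_extrapolate)
        return boxcox_z(y, self.L(x), self.M(x), self.S(x))

    def centile_at(self, x, alpha, *, allow_extrapolate: bool = False):
        self._check_range(x, allow_extrapolate)
        return centile(alpha, self.L(x), self.M(x), self.S(x))

    def reference_table(
        self,
        centiles=DEFAULT_CENTILES,
        grid=None,
        *,
        num: int = 50,
        allow_extrapolate: bool = False,
    ) -> PercentileTable:
        """Tabulate centile curves on a covariate grid inside the fit range."""
        lo, hi = self.x_range
        if grid is None:
            grid = np.linspace(lo, hi, num)
        grid = np.asarray(grid, dtype=float)
        self._check_range(grid, allow_extrapolate)
        levels = tuple(sorted(float(c) for c in centiles))
        cols = {}
        for a in levels:
            cols[a] = centile(a, self.L(grid), self.M(grid), self.S(grid))
        values = pd.DataFrame(cols, index=pd.Index(grid, name=self.model.xname))
        values.columns = [f"P{100 * a:g}" for a in levels]
        arr = values.to_numpy()
        if arr.shape[1] > 1 and not np.all(np.diff(arr, axis=1) > 0):
            raise AssertionError("centile columns are not strictly increasing")
        return PercentileTable(
            covariate=self.model.xname, grid=grid, levels=levels,
            values=values, stratum=self.model.stratum,
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lo, hi = self.x_range
        lines = [
            "LMS (Box-Cox Cole-Green) reference model",
            "=" * 44,
            f"outcome:    {m.yname}",
            f"covariate:  {m.xname}  range [{lo:.4g}, {hi:.4g}]",
            f"stratum:    {m.stratum or '-'}",
            f"n:          {self.n}",
            f"dfs (L,M,S): {m.dfs}   effective df: {self.edf_total:.2f}",
            f"loglik:     {self.loglik:.3f}",
            f"BIC:        {self.bic:.3f}",
            f"converged:  {self.converged}",
            "-" * 44,
        ]
        mid = 0.5 * (lo + hi)
        for xv in (lo, mid, hi):
            lines.append(
                f"  x={xv:8.3f}  L={float(self.L(xv)):7.3f}  "
                f"M={float(self.M(xv)):9.4f}  S={float(self.S(xv)):7.4f}"
            )
        return "\n".join(lines)

    def plot_centiles(self, centiles=DEFAULT_CENTILES, ax=None, *,
                      show_data: bool = True, num: int = 100):
        """Draw the centile fan; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        table = self.reference_table(centiles, num=num)
        for col in table.values.columns:
            ax.plot(table.grid, table.values[col], lw=1.2,
                    color="C0" if col == "P50" else "gray")
            ax.annotate(col, (table.grid[-1], table.values[col].iloc[-1]),
                        fontsize=7, va="center")
        if show_data:
            ax.scatter(self.model.x, self.model.y, s=8, alpha=0.4, color="C3")
        ax.set_xlabel(self.model.xname)
        ax.set_ylabel(self.model.yname)
        title = f"{self.model.yname} centiles"
        if self.model.stratum:
            title += f" ({self.model.stratum})"
        ax.set_title(title)
        return ax

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "outcome": self.model.yname,
            "covariate": self.model.xname,
            "stratum": self.model.stratum,
            "n": self.n,
            "dfs": list(self.model.dfs),
            "x_range": list(self.x_range),
            "loglik": self.loglik,
            "edf_total": self.edf_total,
            "bic": self.bic,
            "converged": self.converged,
            "curves": {k: c.to_dict() for k, c in self.curves.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_model(path) -> "FrozenLMSResults":
    """Load a saved model for scoring new measurements."""
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return FrozenLMSResults(d)


class FrozenLMSResults:
    """Read-only view of a serialized LMS model (scoring and tabulation)."""

    def __init__(self, d: dict):
        self._d = d
        self.curves = {k: ParamCurve.from_dict(c) for k, c in d["curves"].items()}
        self.outcome = d["outcome"]
        self.covariate = d["covariate"]
        self.stratum = d.get("stratum")
        self.x_range = tuple(d["x_range"])

    def L(self, x):
        return self.curves["L"].value(x)

    def M(self, x):
        return self.curves["M"].value(x)

    def S(self, x):
        return self.curves["S"].value(x)

    def zscore(self, x, y, *, allow_extrapolate: bool = False):
        x = np.asarray(x, dtype=float)
        lo, hi = self.x_range
        if not allow_extrapolate and (np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9)):
            raise ValueError(f"covariate outside fitted range [{lo:g}, {hi:g}]")
        return boxcox_z(y, self.L(x), self.M(x), self.S(x))


# ---------------------------------------------------------------------------
# Functional interface
# ---------------------------------------------------------------------------

def fit_lms(x, y, dfs=(0, 2, 0), **kw) -> LMSResults:
    """Fit an LMS model; see :class:`LMS` for parameters."""
    return LMS(x, y, dfs, **kw).fit()


def df_grid_search(x, y, grid=None, **kw) -> tuple[LMSResults, pd.DataFrame]:
    """Fit every df triple in `grid` and return the lowest-BIC model.

    `grid` is an iterable of ``(df_L, df_M, df_S)`` triples; the default is
    the full {0..5}^3 lattice.  Ties in BIC break toward smaller total df,
    then grid order.  Cells whose fit fails or does not converge are kept in
    the returned table but excluded from the argmin.
    """
    if grid is None:
        grid = itertools.product(range(6), repeat=3)
    rows, results = [], []
    for i, dfs in enumerate(grid):
        row = {"df_L": dfs[0], "df_M": dfs[1], "df_S": dfs[2]}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = fit_lms(x, y, dfs, **kw)
            row.update(
                edf=res.edf_total, loglik=res.loglik, bic=res.bic,
                converged=res.converged, error="",
            )
            results.append((res, i))
        except Exception as exc:  # noqa: BLE001 - cell-level failure is data
            row.update(edf=np.nan, loglik=np.nan, bic=np.nan,
                       converged=False, error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    usable = [(r, i) for r, i in results if r.converged]
    if not usable:
        raise RuntimeError("no grid cell converged")
    best, _ = min(usable, key=lambda t: (t[0].bic, sum(t[0].model.dfs), t[1]))
    return best, table


def cross_validate_lms(x, y, dfs, k_folds: int = 10, seed: int = 0, **kw) -> float:
    """k-fold mean held-out BCCG log-likelihood per observation.

    Folds are a seeded permutation split; each fold's model is fitted on the
    remaining data and evaluated on the held-out observations (covariates
    clipped to the training range).  Folds whose fit fails are dropped with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if k_folds < 2 or k_folds > x.size:
        raise ValueError(f"k_folds must be in [2, n], got {k_folds}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(x.size)
    folds = np.array_split(idx, k_folds)
    total_ll, total_n = 0.0, 0
    for i, test in enumerate(folds):
        train = np.setdiff1d(idx, test, assume_unique=False)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = fit_lms(x[train], y[train], dfs, **kw)
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"fold {i} dropped: {exc}", RuntimeWarning, stacklevel=2)
            continue
        xt = np.clip(x[test], *res.x_range)
        total_ll += float(np.sum(
            _bccg_loglik_terms(y[test], res.L(xt), res.M(xt), res.S(xt))
        ))
        total_n += test.size
    if total_n == 0:
        raise RuntimeError("all cross-validation folds failed")
    return total_ll / total_n


def reference_table(model: LMSResults, centiles=DEFAULT_CENTILES, grid=None,
                    **kw) -> PercentileTable:
    """Functional alias for :meth:`LMSResults.reference_table`."""
    return model.reference_table(centiles, grid, **kw)


def zscore_of(model: LMSResults, x, y, **kw):
    """Functional alias for :meth:`LMSResults.zscore`."""
    return model.zscore(x, y, **kw)
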