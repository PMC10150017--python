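"""Two-stage covariate subset selection for reference-chart construction.

Stage one is greedy forward selection within an ordinary-least-squares
framework: starting from the intercept-only model, the single candidate
whose addition most lowers the AIC is added, until no addition lowers it.
K-fold cross-validated prediction error is computed along the path so
subsets of different sizes can be compared on held-out error.

Stage two decides how many of the path's covariates are *significant*: for
each prefix size q, a residual-resampling bootstrap tests whether adding
the (q+1)-th path covariate reduces the residual sum of squares more than
chance.  The chosen subset is the shortest prefix whose extension is no
longer significant at level alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ForwardSelection",
    "SelectionResult",
    "forward_path",
    "cv_compare",
    "bootstrap_qtest",
    "select_covariates",
]


@dataclass(frozen=True)
class SelectionResult:
    """Selected covariate subset with the full AIC / CV / bootstrap trace."""

    outcome: str
    candidates: list[str]
    path: list[str]
    aic_trace: list[float]       # AIC after each addition (index 0 = intercept)
    cv_scores: dict[int, float]  # prefix size -> k-fold mean squared error
    bootstrap_p: dict[int, float]
    chosen_q: int
    chosen_subset: list[str]
    alpha: float
    B: int
    k_folds: int
    seed: int
    n_used: int
    n_dropped: int
    cv_disagrees: bool = False

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "candidates": self.candidates,
            "path": self.path,
            "aic_trace": self.aic_trace,
            "cv_scores": {str(k): v for k, v in self.cv_scores.items()},
            "bootstrap_p": {str(k): v for k, v in self.bootstrap_p.items()},
            "chosen_q": self.chosen_q,
            "chosen_subset": self.chosen_subset,
            "alpha": self.alpha,
            "B": self.B,
            "k_folds": self.k_folds,
            "seed": self.seed,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "cv_disagrees": self.cv_disagrees,
        }

    def summary(self) -> str:
        lines = [
            f"Forward selection for outcome {self.outcome!r}",
            "=" * 48,
            f"n used: {self.n_used}  (dropped {self.n_dropped} incomplete rows)",
            f"candidates: {', '.join(self.candidates)}",
            "",
            "step  covariate        AIC",
            f"   0  <intercept>      {self.aic_trace[0]:.2f}",
        ]
        for i, (name, aic) in enumerate(zip(self.path, self.aic_trace[1:]), 1):
            lines.append(f"  {i:2d}  {name:<15s}  {aic:.2f}")
        lines.append("")
        lines.append("size  CV-MSE       bootstrap p")
        for q in sorted(self.cv_scores):
            p = self.bootstrap_p.get(q)
            ptxt = f"{p:.4f}" if p is not None else "-"
            mark = " <- chosen" if q == self.chosen_q else ""
            lines.append(f"  {q:2d}  {self.cv_scores[q]:<11.5g}  {ptxt}{mark}")
        lines.append("")
        lines.append(f"chosen subset (q={self.chosen_q}): "
                     f"{{{', '.join(self.chosen_subset) or ''}}}")
        if self.cv_disagrees:
            lines.append("note: cross-validation favored a larger prefix; the "
                         "bootstrap decision was kept")
        return "\n".join(lines)


def _design(X: pd.DataFrame, cols: list[str]) -> np.ndarray:
    n = len(X)
    if not cols:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n)] + [X[c].to_numpy(float) for c in cols])


def forward_path(y, X: pd.DataFrame) -> tuple[list[str], list[float]]:
    """Greedy forward selection under AIC.

    At each step the single candidate minimizing the AIC of the OLS fit is
    added; the path stops when no addition lowers the AIC.  Ties break by
    column declaration order.  Candidates whose addition makes the design
    rank-deficient are skipped with a warning.

    Returns the ordered path and the AIC trace (entry 0 is the
    intercept-only AIC).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y and X must have equal length")
    if len(y) < X.shape[1] + 2:
        raise ValueError("need at least 2 more rows than candidates")
    current: list[str] = []
    remaining = list(X.columns)
    aic_now = float(sm.OLS(y, _design(X, current)).fit().aic)
    trace = [aic_now]
    path: list[str] = []
    while remaining:
        best_name, best_aic = None, aic_now
        for name in remaining:
            design = _design(X, current + [name])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                warnings.warn(
                    f"skipping {name!r}: design becomes rank-deficient",
                    RuntimeWarning, stacklevel=2,
                )
                continue
            aic = float(sm.OLS(y, design).fit().aic)
            if aic < best_aic - 1e-12:
                best_name, best_aic = name, aic
        if best_name is None:
            break
        current.append(best_name)
        remaining.remove(best_name)
        path.append(best_name)
        trace.append(best_aic)
        aic_now = best_aic
    return path, trace


def _fold_indices(n, k_folds, seed, y, max_retries=5):
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        folds = np.array_split(rng.permutation(n), k_folds)
        ok = all(np.ptp(np.delete(y, f)) > 0 for f in folds)
        if ok:
            if attempt:
                warnings.warn(
                    "refolded cross-validation split (zero-variance fold)",
                    RuntimeWarning, stacklevel=3,
                )
            return folds
    raise RuntimeError("could not build folds with non-degenerate outcome")


def cv_compare(y, X: pd.DataFrame, path: list[str], k_folds: int = 10,
               seed: int = 0) -> dict[int, float]:
    """k-fold mean squared prediction error for each prefix of the path."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k_folds < 2 or n < 2 * k_folds:
        raise ValueError(f"need k_folds >= 2 and n >= 2*k_folds (n={n}, k={k_folds})")
    folds = _fold_indices(n, k_folds, seed, y)
    scores: dict[int, float] = {}
    for q in range(len(path) + 1):
        cols = path[:q]
        sse = 0.0
        for test in folds:
            train = np.setdiff1d(np.arange(n), test)
            A = _design(X.iloc[train], cols)
            beta, *_ = np.linalg.lstsq(A, y[train], rcond=None)
            pred = _design(X.iloc[test], cols) @ beta
            sse += float(np.sum((y[test] - pred) ** 2))
        scores[q] = sse / n
    return scores


def bootstrap_qtest(y, X: pd.DataFrame, path: list[str], q: int,
                    B: int = 500, seed: int = 0,
                    candidates: list[str] | None = None) -> float:
    """Residual-resampling bootstrap test of "the size-q prefix suffices".

    The statistic is the drop in residual sum of squares achieved by the
    forward step after the size-q prefix — i.e. the best single addition
    among the remaining candidates (which is exactly the (q+1)-th path
    covariate).  The null distribution resamples centered residuals of the
    size-q fit, rebuilds y*, and *redoes the forward step* on each
    resample, so the maximal nature of the statistic is reflected in the
    reference distribution; ``p = (1 + #{T* >= T_obs}) / (B + 1)``.

    Passing an explicit single-element ``candidates`` list turns this into
    the test of one prespecified addition.
    """
    if not 0 <= q < len(path):
        raise ValueError(f"q must be in [0, len(path)), got {q}")
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    y = np.asarray(y, dtype=float)
    n = len(y)
    prefix = path[:q]
    if candidates is None:
        candidates = [c for c in X.columns if c not in prefix]
    if not candidates:
        raise ValueError("no candidates to test beyond the prefix")
    A0 = _design(X, prefix)
    Q0, _ = np.linalg.qr(A0)
    fit0 = Q0 @ (Q0.T @ y)
    resid = y - fit0
    rss0 = float(np.sum(resid**2))
    if rss0 < 1e-12 * max(1.0, float(np.sum(y**2))):
        warnings.warn("degenerate residuals in bootstrap test; p = 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    # adding one column x_c to the orthonormal basis Q0 drops the RSS by
    # (v_c' y)^2, with v_c the unit-norm residual of x_c against Q0
    V = []
    for c in candidates:
        xc = X[c].to_numpy(float)
        v = xc - Q0 @ (Q0.T @ xc)
        nv = np.linalg.norm(v)
        if nv < 1e-10 * max(1.0, np.linalg.norm(xc)):
            continue  # collinear with the prefix: no possible improvement
        V.append(v / nv)
    if not V:
        return 1.0
    V = np.column_stack(V)
    t_obs = float(np.max((V.T @ y) ** 2))
    centered = resid - resid.mean()
    rng = np.random.default_rng(seed)
    Estar = centered[rng.integers(0, n, size=(n, B))]
    Ystar = fit0[:, None] + Estar
    t_star = np.max((V.T @ Ystar) ** 2, axis=0)
    return float((1 + np.sum(t_star >= t_obs)) / (B + 1))


class ForwardSelection:
    """Model object bundling the two-stage selection for one outcome.

    Parameters
    ----------
    y
        Outcome values.
    X
        Candidate covariate table (numeric columns; binary covariates coded
        0/1 by the caller).  Rows with any missing value in y or X are
        dropped (complete-case analysis) and counted.
    alpha, B, k_folds, seed
        Bootstrap significance level, replicate count, CV fold count, and
        the master seed all derived randomness flows from.
    """

    def __init__(self, y, X: pd.DataFrame, *, outcome: str = "y",
                 alpha: float = 0.05, B: int = 500, k_folds: int = 10,
                 seed: int = 0):
        y = np.asarray(y, dtype=float)
        X = X.copy()
        mask = np.isfinite(y) & np.isfinite(X.to_numpy(float)).all(axis=1)
        self.n_dropped = int((~mask).sum())
        self.y = y[mask]
        self.X = X.loc[mask].reset_index(drop=True)
        self.outcome = outcome
        self.alpha, self.B, self.k_folds, self.seed = alpha, B, k_folds, seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str,
                       candidates: list[str], **kw) -> "ForwardSelection":
        return cls(df[outcome].to_numpy(float), df[candidates],
                   outcome=outcome, **kw)

    def fit(self) -> SelectionResult:
        path, trace = forward_path(self.y, self.X)
        ss = np.random.SeedSequence(self.seed)
        cv_seed, boot_seed = (int(s.generate_state(1)[0] % (2**31))
                              for s in ss.spawn(2))
        cv_scores = cv_compare(self.y, self.X, path, self.k_folds, cv_seed)

        bootstrap_p: dict[int, float] = {}
        chosen_q = len(path)
        for q in range(len(path)):
            p = bootstrap_qtest(self.y, self.X, path, q, self.B,
                                boot_seed + q)
            bootstrap_p[q] = p
            if p >= self.alpha:
                chosen_q = q
                break

        cv_best = min(cv_scores, key=lambda k: (cv_scores[k], k))
        cv_disagrees = cv_best > chosen_q
        if cv_disagrees:
            warnings.warn(
                f"cross-validation favors prefix size {cv_best} over the "
                f"bootstrap choice {chosen_q}; keeping the bootstrap choice",
                RuntimeWarning, stacklevel=2,
            )
        return SelectionResult(
            outcome=self.outcome,
            candidates=list(self.X.columns),
            path=path,
            aic_trace=trace,
            cv_scores=cv_scores,
            bootstrap_p=bootstrap_p,
            chosen_q=chosen_q,
            chosen_subset=path[:chosen_q],
            alpha=self.alpha,
            B=self.B,
            k_folds=self.k_folds,
            seed=self.seed,
            n_used=len(self.y),
            n_dropped=self.n_dropped,
            cv_disagrees=cv_disagrees,
        )


def select_covariates(y, X: pd.DataFrame, alpha: float = 0.05, B: int = 500,
                      k_folds: int = 10, seed: int = 0,
                      outcome: str = "y") -> SelectionResult:
    """Functional wrapper around :class:`ForwardSelection`."""
    return ForwardSelection(y, X, outcome=outcome, alpha=alpha, B=B,
                            k_folds=k_folds, seed=seed).fit()
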