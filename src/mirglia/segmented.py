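"""Segmented (broken-line) regression for expression-versus-distance profiles.

Estimates where a gene's expression changes slope as a function of distance
to the nearest amyloid deposit, using the iterative linearization of Muggeo:
the piecewise-linear model

    y = b0 + b1 * d + sum_k [ b2_k * (d - psi_k)_+ + g_k * V_k ],
    V_k = -1{d > psi_k},

is refit with the breakpoints held fixed, and each breakpoint is updated by
``psi_k <- psi_k + g_k / b2_k`` until the working coefficients ``g_k``
vanish.  The estimator is scikit-learn compatible (``fit`` / ``predict`` /
``get_params``) and selects the number of breakpoints (0..n_breakpoints) by
BIC unless told otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from mirglia.exceptions import ParameterError


@dataclass(frozen=True)
class BreakpointFit:
    """One gene's change-point estimate with its uncertainty."""

    gene: str
    psi_hat: float
    ci_low: float
    ci_high: float
    slopes: tuple[float, ...]
    converged: bool
    n_iterations: int
    n_breakpoints: int
    bic: float


def _design(d: np.ndarray, psi: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(d), d]
    for p in psi:
        cols.append(np.clip(d - p, 0.0, None))
    for p in psi:
        cols.append(-(d > p).astype(float))
    return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


class SegmentedRegression(RegressorMixin, BaseEstimator):
    """Piecewise-linear regression with estimated breakpoints.

    Parameters
    ----------
    n_breakpoints : int, default=1
        Maximum number of slope changes to consider.
    select_by_bic : bool, default=True
        Compare models with 0..n_breakpoints breaks by BIC and keep the
        best; with False the model always has ``n_breakpoints`` breaks.
    tol : float, default=1e-4
        Convergence threshold on the largest breakpoint update (same units
        as the predictor, here micrometres).
    max_iter : int, default=50
        Iteration cap per start.
    n_grid : int, default=9
        Number of interior quantiles (deciles by default) used as starting
        breakpoint values.

    Attributes
    ----------
    psi_ : ndarray of shape (k,)
        Estimated breakpoints, sorted, ``k <= n_breakpoints``.
    psi_se_ : ndarray of shape (k,)
        Delta-method standard errors ``SE(g) / |b2|``.
    ci_ : ndarray of shape (k, 2)
        95% Wald intervals for each breakpoint.
    slopes_ : ndarray of shape (k + 1,)
        Segment slopes, left to right.
    intercept_ : float
    converged_ : bool
    n_iter_ : int
    bic_ : float
        BIC of the selected model.
    sse_ : float
        Residual sum of squares of the selected model.
    """

    def __init__(
        self,
        n_breakpoints: int = 1,
        select_by_bic: bool = True,
        tol: float = 1e-4,
        max_iter: int = 50,
        n_grid: int = 9,
    ) -> None:
        self.n_breakpoints = n_breakpoints
        self.select_by_bic = select_by_bic
        self.tol = tol
        self.max_iter = max_iter
        self.n_grid = n_grid

    # -- fitting -----------------------------------------------------------

    def _fit_from(self, d, y, psi0):
        """Run the Muggeo iteration from one starting breakpoint vector."""
        lo, hi = d.min(), d.max()
        psi = np.sort(np.asarray(psi0, dtype=float))
        k = psi.size
        n_iter = 0
        converged = False
        beta = None
        for n_iter in range(1, self.max_iter + 1):
            X = _design(d, psi)
            beta, _ = _ols(X, y)
            b2 = beta[2 : 2 + k]
            gamma = beta[2 + k : 2 + 2 * k]
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(np.abs(b2) > 1e-12, gamma / b2, 0.0)
            new_psi = np.sort(psi + step)
            if (new_psi <= lo).any() or (new_psi >= hi).any() or (np.diff(new_psi) <= 0).any():
                return None  # left the admissible region
            delta = np.max(np.abs(new_psi - psi))
            psi = new_psi
            if delta < self.tol:
                converged = True
                break
        X = _design(d, psi)
        beta, sse = _ols(X, y)
        return {"psi": psi, "beta": beta, "sse": sse, "X": X,
                "converged": converged, "n_iter": n_iter}

    def _starts(self, d, k):
        qs = np.quantile(d, np.linspace(0.1, 0.9, self.n_grid))
        qs = np.unique(qs)
        if k == 1:
            return [[q] for q in qs]
        # keep the start count modest for k >= 2
        picks = qs[:: max(1, len(qs) // 5)]
        return [list(c) for c in itertools.combinations(picks, k)]

    @staticmethod
    def _bic(n: int, sse: float, k_breaks: int) -> float:
        n_params = 2 + 2 * k_breaks  # intercept, base slope, slope diffs, breaks
        sse = max(sse, 1e-300)
        return n * np.log(sse / n) + n_params * np.log(n)

    def fit(self, X, y):
        d = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if d.size != y.size:
            raise ParameterError("X and y must have equal length")
        if d.size < 10:
            raise ParameterError("need at least 10 points to fit a breakpoint")
        if np.ptp(d) <= 0:
            raise ParameterError("distances must span a positive range")
        if self.n_breakpoints < 0:
            raise ParameterError("n_breakpoints must be >= 0")

        n = d.size
        # 0-break straight line, always available
        X0 = np.column_stack([np.ones(n), d])
        beta0, sse0 = _ols(X0, y)
        candidates = {0: {"psi": np.empty(0), "beta": beta0, "sse": sse0, "X": X0,
                          "converged": True, "n_iter": 0}}
        if np.ptp(y) > 0:  # constant response degenerates to the no-break line
            ks = range(1, self.n_breakpoints + 1)
            for k in ks:
                best = None
                for start in self._starts(d, k):
                    fit = self._fit_from(d, y, start)
                    if fit is None:
                        continue
                    if best is None or (fit["converged"], -fit["sse"]) > (
                        best["converged"], -best["sse"]
                    ):
                        best = fit
                if best is not None:
                    candidates[k] = best

        bics = {k: self._bic(n, c["sse"], k) for k, c in candidates.items()}
        if self.select_by_bic or self.n_breakpoints not in candidates:
            k_sel = min(bics, key=bics.get)
        else:
            k_sel = self.n_breakpoints
        sel = candidates[k_sel]

        psi, beta = sel["psi"], sel["beta"]
        k = psi.size
        self.psi_ = psi
        self.intercept_ = float(beta[0])
        self.slopes_ = np.cumsum(np.concatenate([[beta[1]], beta[2 : 2 + k]]))
        self.converged_ = bool(sel["converged"])
        self.n_iter_ = int(sel["n_iter"])
        self.sse_ = float(sel["sse"])
        self.bic_ = float(bics[k_sel])
        self.bic_by_k_ = {kk: float(v) for kk, v in bics.items()}
        self.coef_ = beta[1 : 2 + k].copy()
        self.n_features_in_ = 1

        if k > 0:
            Xf = sel["X"]
            dof = max(n - Xf.shape[1], 1)
            sigma2 = sel["sse"] / dof
            xtx_inv = np.linalg.pinv(Xf.T @ Xf)
            se_all = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
            b2 = beta[2 : 2 + k]
            se_gamma = se_all[2 + k : 2 + 2 * k]
            with np.errstate(divide="ignore"):
                self.psi_se_ = np.where(np.abs(b2) > 1e-12, se_gamma / np.abs(b2), np.inf)
            half = 1.959963984540054 * self.psi_se_
            self.ci_ = np.column_stack([psi - half, psi + half])
        else:
            self.psi_se_ = np.empty(0)
            self.ci_ = np.empty((0, 2))
        return self

    def predict(self, X):
        check_is_fitted(self, "psi_")
        d = np.asarray(X, dtype=float).reshape(-1)
        out = np.full(d.shape, self.intercept_, dtype=float)
        out += self.slopes_[0] * d
        for p, db in zip(self.psi_, np.diff(self.slopes_)):
            out += db * np.clip(d - p, 0.0, None)
        return out


def fit_breakpoint(
    distances,
    expression,
    n_breakpoints: int = 1,
    gene: str = "",
    **kwargs,
) -> BreakpointFit:
    """Fit a segmented regression and return a :class:`BreakpointFit` record.

    When BIC prefers the no-break line the fit reports ``psi_hat = nan`` and
    zero breakpoints; with more than one break the first (smallest-distance)
    breakpoint is reported in ``psi_hat``.
    """
    model = SegmentedRegression(n_breakpoints=n_breakpoints, **kwargs).fit(distances, expression)
    if model.psi_.size:
        psi, (lo, hi) = float(model.psi_[0]), model.ci_[0]
    else:
        psi, lo, hi = float("nan"), float("nan"), float("nan")
    return BreakpointFit(
        gene=gene,
        psi_hat=psi,
        ci_low=float(lo),
        ci_high=float(hi),
        slopes=tuple(float(s) for s in model.slopes_),
        converged=model.converged_,
        n_iterations=model.n_iter_,
        n_breakpoints=int(model.psi_.size),
        bic=model.bic_,
    )
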