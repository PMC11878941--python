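"""Weibull psychometric fitting and direction-range threshold (DRT) extraction.

Probability correct as a function of direction range R is modeled with a
*decreasing* Weibull bounded by chance gamma and lapse-limited ceiling
1 - lambda::

    psi(R) = gamma + (1 - gamma - lambda) * exp(-(R / alpha)**beta)

Larger R means a harder task, so psi falls from 1 - lambda at R = 0 toward
gamma as R grows.  (alpha, beta) are estimated by maximizing the binomial
log-likelihood of per-level correct counts with gamma and lambda held fixed
(lambda = 0.05 by default).  The DRT is the range at which psi crosses the
criterion halfway between chance and the lapse-limited ceiling,
c = ((1 - lambda) + gamma) / 2; for this halfway criterion the threshold has
the closed form R* = alpha * (ln 2)**(1/beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = [
    "LevelCounts",
    "PsychometricFit",
    "psychometric_p",
    "aggregate",
    "fit_weibull",
    "criterion",
    "drt",
    "WeibullThreshold",
]

_COMPONENT_COLUMNS = {
    "vertical": "v_correct",
    "horizontal": "h_correct",
    "combined": "combined_correct",
}


def psychometric_p(
    range_deg, alpha: float, beta: float, gamma: float = 0.5, lapse: float = 0.05
):
    """Probability correct at direction range ``range_deg`` (vectorized).

    Monotone non-increasing in R; equals ``1 - lapse`` at R = 0 and tends to
    ``gamma`` as R grows.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be strictly positive")
    r = np.asarray(range_deg, dtype=float)
    if np.any(r < 0):
        raise ValueError("direction range must be non-negative")
    p = gamma + (1.0 - gamma - lapse) * np.exp(-((r / alpha) ** beta))
    return p if p.ndim else float(p)


def criterion(gamma: float, lapse: float) -> float:
    """Percent-correct criterion defining the DRT: ((1 - lapse) + gamma) / 2."""
    if not (0.0 <= gamma < 1.0 - lapse <= 1.0):
        raise ValueError(f"require 0 <= gamma < 1 - lapse <= 1, got {gamma}, {lapse}")
    return ((1.0 - lapse) + gamma) / 2.0


@dataclass
class LevelCounts:
    """Per-level binomial counts for one component judgment."""

    range_deg: np.ndarray
    n_trials: np.ndarray
    n_correct: np.ndarray
    component: str = "vertical"

    def __post_init__(self) -> None:
        self.range_deg = np.asarray(self.range_deg, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.n_correct = np.asarray(self.n_correct, dtype=int)
        if not (len(self.range_deg) == len(self.n_trials) == len(self.n_correct)):
            raise ValueError("level arrays must have equal length")
        if np.any(self.n_correct < 0) or np.any(self.n_correct > self.n_trials):
            raise ValueError("require 0 <= n_correct <= n_trials at every level")

    def nonempty(self) -> "LevelCounts":
        """Drop levels with zero trials (they carry no likelihood)."""
        keep = self.n_trials > 0
        return LevelCounts(
            self.range_deg[keep], self.n_trials[keep], self.n_correct[keep],
            self.component,
        )


@dataclass
class PsychometricFit:
    """Fitted Weibull parameters and the derived threshold."""

    alpha: float
    beta: float
    gamma: float
    lapse: float
    loglik: float
    converged: bool
    drt_deg: float

    def predict(self, range_deg):
        """psi(R) under the fitted parameters."""
        return psychometric_p(range_deg, self.alpha, self.beta, self.gamma, self.lapse)

    def threshold(self, p: float | None = None) -> float:
        """Range at which psi crosses ``p`` (default: the halfway criterion)."""
        c = criterion(self.gamma, self.lapse) if p is None else p
        frac = (c - self.gamma) / (1.0 - self.gamma - self.lapse)
        if not 0.0 < frac < 1.0:
            raise ValueError(f"criterion {c} outside the open range (gamma, 1-lapse)")
        return self.alpha * (-np.log(frac)) ** (1.0 / self.beta)


def aggregate(trials: pd.DataFrame, component: str = "vertical") -> LevelCounts:
    """Tally per-level correct counts for one component from a trial log.

    ``trials`` needs ``direction_range_deg`` plus the relevant correctness
    column (``v_correct``/``h_correct``/``combined_correct``); aborted rows
    (``aborted`` truthy) are excluded.
    """
    if component not in _COMPONENT_COLUMNS:
        raise ValueError(f"unknown component {component!r}")
    df = trials
    if "aborted" in df.columns:
        df = df[~df["aborted"].astype(bool)]
    if len(df) == 0:
        raise ValueError("no scored trials to aggregate")
    col = _COMPONENT_COLUMNS[component]
    grouped = df.groupby("direction_range_deg")[col]
    counts = grouped.agg(["count", "sum"]).reset_index()
    return LevelCounts(
        counts["direction_range_deg"].to_numpy(float),
        counts["count"].to_numpy(int),
        counts["sum"].to_numpy(float).round().astype(int),
        component,
    )


def _negloglik(params, r, n, k, gamma, lapse):
    alpha = np.exp(params[0])
    beta = np.exp(params[1])
    psi = gamma + (1.0 - gamma - lapse) * np.exp(-((r / alpha) ** beta))
    psi = np.clip(psi, 1e-12, 1.0 - 1e-12)
    return -np.sum(k * np.log(psi) + (n - k) * np.log1p(-psi))


_LOG_ALPHA_BOUNDS = (np.log(1e-2), np.log(1e5))
_LOG_BETA_BOUNDS = (np.log(0.05), np.log(50.0))


def fit_weibull(
    counts: LevelCounts,
    gamma: float = 0.5,
    lapse: float = 0.05,
    n_starts: int = 5,
) -> PsychometricFit:
    """Maximum-likelihood Weibull fit of per-level counts with fixed gamma/lapse.

    Optimizes the binomial log-likelihood over (alpha, beta) in log space
    (L-BFGS-B) from ``n_starts`` multistarts over a log-spaced alpha grid.
    Degenerate data — fewer than two informative levels, or all-correct /
    all-incorrect counts — yield ``converged=False`` rather than an error.
    """
    criterion(gamma, lapse)  # validates gamma/lapse jointly
    counts = counts.nonempty()
    r, n, k = counts.range_deg, counts.n_trials, counts.n_correct
    degenerate = (
        len(r) < 2 or np.all(k == n) or np.all(k == 0)
    )
    if degenerate:
        return PsychometricFit(np.nan, np.nan, gamma, lapse, np.nan, False, np.nan)

    r_max = float(r.max()) if r.max() > 0 else 100.0
    alpha_starts = np.geomspace(0.1 * r_max, 5.0 * r_max, n_starts)
    best = None
    for a0 in alpha_starts:
        res = minimize(
            _negloglik,
            x0=np.array([np.log(a0), np.log(2.0)]),
            args=(r, n, k, gamma, lapse),
            method="L-BFGS-B",
            bounds=[_LOG_ALPHA_BOUNDS, _LOG_BETA_BOUNDS],
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha = float(np.exp(best.x[0]))
    beta = float(np.exp(best.x[1]))
    fit = PsychometricFit(
        alpha, beta, gamma, lapse, -float(best.fun), bool(best.success), np.nan
    )
    if fit.converged:
        fit.drt_deg = fit.threshold()
    return fit


def drt(fit: PsychometricFit) -> float:
    """Direction-range threshold of a converged fit (deg)."""
    if not fit.converged:
        raise ValueError("cannot extract a threshold from a non-converged fit")
    return fit.threshold()


class WeibullThreshold(BaseEstimator):
    """Scikit-learn style estimator for the Weibull psychometric fit.

    Parameters
    ----------
    gamma : float, default 0.5
        Chance level (0.5 for a component judgment, 0.25 for the combined
        4AFC judgment).
    lapse : float, default 0.05
        Fixed lapse rate.
    n_starts : int, default 5
        Multistarts over the alpha grid.

    Attributes (after ``fit``)
    --------------------------
    alpha_, beta_ : fitted Weibull scale (deg) and shape.
    drt_ : direction-range threshold at the halfway criterion (deg).
    loglik_ : binomial log-likelihood at the optimum.
    converged_ : whether the data supported a fit.
    """

    def __init__(self, gamma: float = 0.5, lapse: float = 0.05, n_starts: int = 5):
        self.gamma = gamma
        self.lapse = lapse
        self.n_starts = n_starts

    def fit(self, X, y):
        """Fit from per-trial data: X = direction range (deg), y = correct (0/1)."""
        r = np.asarray(X, dtype=float).reshape(-1)
        correct = np.asarray(y).astype(bool)
        if r.shape != correct.shape:
            raise ValueError("X and y must have the same length")
        if len(r) == 0:
            raise ValueError("empty training data")
        levels, inverse = np.unique(r, return_inverse=True)
        n = np.bincount(inverse, minlength=len(levels))
        k = np.bincount(inverse, weights=correct.astype(float), minlength=len(levels))
        counts = LevelCounts(levels, n, k.round().astype(int))
        result = fit_weibull(counts, self.gamma, self.lapse, self.n_starts)
        self.alpha_ = result.alpha
        self.beta_ = result.beta
        self.loglik_ = result.loglik
        self.converged_ = result.converged
        self.drt_ = result.drt_deg
        self.fit_result_ = result
        return self

    def predict_proba(self, X):
        """P(incorrect), P(correct) at each direction range."""
        p = self.fit_result_.predict(np.asarray(X, dtype=float).reshape(-1))
        return np.column_stack([1.0 - p, p])

    def threshold(self, p: float | None = None) -> float:
        return self.fit_result_.threshold(p)
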