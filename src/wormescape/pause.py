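"""Sigmoid pause-probability model P(paused | I) = 1 / (1 + (I/I0)^2).

I0, the *pause current*, is the laser current at which a worm is equally
likely to pause or to mount an active escape. It is fitted per worm type by
maximising the Bernoulli likelihood of the observed active/paused labels.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

__all__ = ["pause_probability", "fit_pause_current", "PauseCurrentModel"]

_LOG_BOUNDS = (np.log(1e-2), np.log(1e4))  # search range for I0, mA


def pause_probability(I, I0: float):
    """Probability of the paused state at laser current ``I`` (mA)."""
    if not (np.isfinite(I0) and I0 > 0):
        raise ValueError(f"I0 must be positive and finite, got {I0}")
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("currents must be nonnegative")
    out = 1.0 / (1.0 + (I / I0) ** 2)
    return out if out.ndim else float(out)


def _neg_loglik(log_I0: float, I: np.ndarray, paused: np.ndarray) -> float:
    r2 = (I / np.exp(log_I0)) ** 2
    # log P(p) = -log(1 + r2);  log P(a) = log(r2) - log(1 + r2)
    ll = -np.sum(np.log1p(r2))
    with np.errstate(divide="ignore"):
        ll += np.sum(np.log(r2[~paused]))
    return -ll


def fit_pause_current(
    paused: Sequence[bool], currents_mA: Sequence[float], xtol: float = 1e-9
) -> float:
    """Maximum-likelihood pause current I0 (mA) from active/paused labels.

    1-D bounded search on log I0 over [1e-2, 1e4] mA after a coarse grid
    pre-scan (the likelihood is unimodal in practice; the scan guards
    against flat stretches).
    """
    paused = np.asarray(paused, dtype=bool)
    I = np.asarray(currents_mA, dtype=float)
    if paused.shape != I.shape:
        raise ValueError("labels and currents must have equal length")
    if not paused.any():
        raise ValueError("all trials active: I0 -> 0 boundary, fit undefined")
    if paused.all():
        raise ValueError("all trials paused: I0 -> infinity boundary, fit undefined")

    grid = np.linspace(*_LOG_BOUNDS, 241)
    vals = [_neg_loglik(g, I, paused) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        _neg_loglik,
        bounds=(lo, hi),
        args=(I, paused),
        method="bounded",
        options={"xatol": xtol},
    )
    return float(np.exp(res.x))


class PauseCurrentModel(BaseEstimator):
    """Scikit-learn style estimator for the sigmoid pause model.

    After ``fit(currents_mA, paused)`` the pause current is available as
    ``I0_mA_``; ``predict_proba`` returns the (paused, active) column pair.
    """

    def __init__(self, xtol: float = 1e-9):
        self.xtol = xtol

    def fit(self, currents_mA, paused):
        currents_mA = np.asarray(currents_mA, dtype=float)
        paused = np.asarray(paused, dtype=bool)
        self.I0_mA_ = fit_pause_current(paused, currents_mA, xtol=self.xtol)
        self.n_trials_ = int(currents_mA.size)
        return self

    def predict_proba(self, currents_mA) -> np.ndarray:
        p = np.atleast_1d(pause_probability(currents_mA, self.I0_mA_))
        return np.column_stack([p, 1.0 - p])

    def score(self, currents_mA, paused) -> float:
        """Mean Bernoulli log-likelihood of labels under the fitted model."""
        I = np.asarray(currents_mA, dtype=float)
        paused = np.asarray(paused, dtype=bool)
        return -_neg_loglik(np.log(self.I0_mA_), I, paused) / I.size
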