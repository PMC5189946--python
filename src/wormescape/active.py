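"""Stereotyped escape templates and the current-scaling function.

Active escapes are modelled as a current-scaled stereotyped template with
correlated Gaussian deviations: v ~ N(f(I) u_a, Sigma_a), with the
saturating scaling function

    f(I) = I1 + I / (1 + I / I2),

whose small-current slope is exactly 1 (this pins the template's overall
scale and makes the parameterisation identifiable). I2 = +inf gives the
linear, non-saturating limit. Paused trials are modelled as N(u_p, Sigma_p)
independent of the current.

For fixed (I1, I2) the template and covariance maximising the active-state
likelihood have closed forms (a weighted least-squares projection and the
residual covariance); the two scaling parameters are found by an outer
derivative-free simplex search over (I1, 1/I2) restarted from random
initial points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "ScalingParams",
    "scaling_function",
    "fit_paused_template",
    "template_update",
    "collapse_profiles",
    "ActiveResponseModel",
]

COLLAPSE_FLOOR = 1e-3  # |f(I)| below this excludes a trial from the collapse


@dataclass(frozen=True)
class ScalingParams:
    """Parameters of f(I) = I1 + I / (1 + I/I2); I2 may be +inf (linear f)."""

    I1: float
    I2: float

    def __post_init__(self):
        if not self.I2 > 0:
            raise ValueError(f"I2 must be positive (or +inf), got {self.I2}")


def scaling_function(I, I1: float, I2: float = np.inf):
    """Saturating current-to-amplitude map f(I) = I1 + I / (1 + I/I2)."""
    I = np.asarray(I, dtype=float)
    if not I2 > 0:
        raise ValueError(f"I2 must be positive (or +inf), got {I2}")
    if np.isinf(I2):
        out = I1 + I
    else:
        out = I1 + I / (1.0 + I / I2)
    return out if out.ndim else float(out)


def _apply_ridge(S: np.ndarray, ridge_epsilon: float) -> np.ndarray:
    """Add epsilon * mean(diag) to the diagonal when badly conditioned."""
    S = 0.5 * (S + S.T)
    eigvals = np.linalg.eigvalsh(S)
    if eigvals[-1] <= 0:
        # degenerate (e.g. identical profiles): ridge is the whole matrix
        return S + ridge_epsilon * max(np.mean(np.diag(S)), 1.0) * np.eye(S.shape[0])
    cond = eigvals[-1] / max(eigvals[0], 0.0) if eigvals[0] > 0 else np.inf
    if cond > 1e10:
        S = S + ridge_epsilon * np.mean(np.diag(S)) * np.eye(S.shape[0])
    return S


def fit_paused_template(
    profiles: np.ndarray, ridge_epsilon: float = 1e-6
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean profile and empirical covariance (1/n) of paused trials."""
    V = np.atleast_2d(np.asarray(profiles, dtype=float))
    n = V.shape[0]
    if n < 2:
        raise ValueError("need at least 2 paused trials to estimate the template")
    u_p = V.mean(axis=0)
    R = V - u_p
    Sigma_p = (R.T @ R) / n
    return u_p, _apply_ridge(Sigma_p, ridge_epsilon)


def template_update(
    profiles: np.ndarray,
    currents_mA: np.ndarray,
    I1: float,
    I2: float,
    ridge_epsilon: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray]:
    """Closed-form ML template and residual covariance at fixed (I1, I2).

    u_a = sum_i v_i f(I_i) / sum_i f(I_i)^2 (pointwise), the stationary
    point of the active-state log-likelihood in u_a; Sigma_a is the full
    empirical covariance (1/n) of the residuals v_i - f(I_i) u_a.
    """
    V = np.atleast_2d(np.asarray(profiles, dtype=float))
    I = np.asarray(currents_mA, dtype=float)
    n = V.shape[0]
    if n < 1:
        raise ValueError("need at least 1 active trial")
    f = np.atleast_1d(scaling_function(I, I1, I2))
    denom = float(np.sum(f * f))
    if denom <= 0:
        raise ValueError("all scaling factors f(I_i) are zero; template undefined")
    u_a = (V * f[:, None]).sum(axis=0) / denom
    R = V - f[:, None] * u_a
    Sigma_a = (R.T @ R) / n
    return u_a, _apply_ridge(Sigma_a, ridge_epsilon)


def collapse_profiles(
    profiles: np.ndarray,
    currents_mA: np.ndarray,
    I1: float,
    I2: float,
    floor: float = COLLAPSE_FLOOR,
) -> Tuple[np.ndarray, np.ndarray]:
    """Rescale each active profile by 1/f(I_i) to test template stereotypy.

    Returns (collapsed profiles, indices of retained trials). Trials with
    |f(I_i)| below ``floor`` cannot be rescaled and are excluded with a
    warning.
    """
    V = np.atleast_2d(np.asarray(profiles, dtype=float))
    f = np.atleast_1d(scaling_function(np.asarray(currents_mA, float), I1, I2))
    keep = np.abs(f) > floor
    if not keep.all():
        dropped = np.flatnonzero(~keep).tolist()
        warnings.warn(
            f"excluding {len(dropped)} trial(s) with |f(I)| <= {floor}: {dropped}",
            stacklevel=2,
        )
    return V[keep] / f[keep, None], np.flatnonzero(keep)


def _active_neg_loglik_profile(
    theta: np.ndarray, V: np.ndarray, I: np.ndarray, ridge_epsilon: float
) -> float:
    """Profile objective: -2/n * loglik up to constants = logdet Sigma_a(theta).

    With Sigma_a at its ML value the quadratic-form term is constant, so the
    outer search only has to minimise the log-determinant of the residual
    covariance.
    """
    I1, inv_I2 = theta
    I2 = np.inf if inv_I2 <= 0 else 1.0 / inv_I2
    try:
        _, Sigma_a = template_update(V, I, I1, I2, ridge_epsilon)
        sign, logdet = np.linalg.slogdet(Sigma_a)
    except (ValueError, np.linalg.LinAlgError):
        return np.inf
    if sign <= 0:
        return np.inf
    return logdet


_Q_SCALE = 100.0  # outer search runs over q = 100 / I2 so both axes are O(1-10)


def _objective_scaled(
    x: np.ndarray, V: np.ndarray, I: np.ndarray, ridge_epsilon: float
) -> float:
    # negative q maps to the linear (I2 = inf) boundary, keeping the simplex
    # search unconstrained
    inv_I2 = max(float(x[1]), 0.0) / _Q_SCALE
    return _active_neg_loglik_profile(
        np.array([x[0], inv_I2]), V, I, ridge_epsilon
    )


class ActiveResponseModel(BaseEstimator):
    """ML fit of the active-escape template model v ~ N(f(I) u_a, Sigma_a).

    Nested optimisation: the outer Nelder-Mead simplex search runs over
    (I1, 100/I2), a parameterisation in which both axes have comparable
    scale and the linear I2 = inf regime is the (soft) boundary 100/I2 <= 0,
    while the template and covariance are profiled out in closed form at
    every step. The profiled objective is extremely flat near its valley, so
    a derivative-free search is used; ``n_restarts`` random initial points
    guard against local optima.

    Fitted attributes: ``I1_``, ``I2_`` (may be +inf), ``u_a_`` (template),
    ``Sigma_a_`` (covariance), ``loglik_`` (total active-state
    log-likelihood at the printed normalisation), ``T_eff_``.
    """

    def __init__(
        self,
        n_restarts: int = 10,
        T_eff: Optional[float] = None,
        ridge_epsilon: float = 1e-6,
        quadform_scale: str = "none",
        i1_init_range: Tuple[float, float] = (-100.0, 100.0),
        inv_i2_init_max: float = 0.2,
        random_state: Optional[int] = None,
    ):
        self.n_restarts = n_restarts
        self.T_eff = T_eff
        self.ridge_epsilon = ridge_epsilon
        self.quadform_scale = quadform_scale
        self.i1_init_range = i1_init_range
        self.inv_i2_init_max = inv_i2_init_max
        self.random_state = random_state

    def fit(self, profiles, currents_mA):
        V = np.atleast_2d(np.asarray(profiles, dtype=float))
        I = np.asarray(currents_mA, dtype=float)
        n, d = V.shape
        if n != I.size:
            raise ValueError("profiles and currents disagree in length")
        if n < d + 2:
            logger.info(
                "only %d active trials for a %d-point template; covariance may "
                "need ridging",
                n,
                d,
            )
        rng = np.random.default_rng(self.random_state)
        # coarse grid pre-scan; its best cells seed extra simplex starts so
        # the global basin is found even with few random restarts
        grid_I1 = np.linspace(*self.i1_init_range, 9)
        grid_q = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        scan = [
            (float(_objective_scaled(np.array([a, q]), V, I, self.ridge_epsilon)), a, q)
            for a in grid_I1
            for q in grid_q
        ]
        scan.sort(key=lambda t: t[0])
        starts = [np.array([a, q]) for _, a, q in scan[:3]]
        starts += [
            np.array(
                [
                    rng.uniform(*self.i1_init_range),
                    rng.uniform(0.0, self.inv_i2_init_max) * _Q_SCALE,
                ]
            )
            for _ in range(self.n_restarts)
        ]
        best = None
        n_fail = 0
        for x0 in starts:
            res = minimize(
                _objective_scaled,
                x0,
                args=(V, I, self.ridge_epsilon),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
            )
            if not np.isfinite(res.fun):
                n_fail += 1
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(
                f"active-model optimisation failed in all {self.n_restarts} restarts "
                f"({n_fail} non-finite objectives)"
            )
        I1 = float(best.x[0])
        inv_I2 = max(float(best.x[1]), 0.0) / _Q_SCALE
        # I2 beyond ~1e6 mA (5e3 x the instrument range) is the linear regime
        I2 = np.inf if inv_I2 <= 1e-6 else 1.0 / inv_I2
        u_a, Sigma_a = template_update(V, I, I1, I2, self.ridge_epsilon)
        self.I1_ = float(I1)
        self.I2_ = float(I2)
        self.u_a_ = u_a
        self.Sigma_a_ = Sigma_a
        self.T_eff_ = float(self.T_eff) if self.T_eff is not None else float(d)
        self.n_trials_ = n
        self.loglik_ = float(self.score(V, I) * n)
        return self

    # -- evaluation --------------------------------------------------------
    def scaling(self, currents_mA):
        return scaling_function(currents_mA, self.I1_, self.I2_)

    def log_likelihood(self, profiles, currents_mA) -> np.ndarray:
        """Per-trial active-state Gaussian log-density at the fitted model."""
        from .decode import gaussian_profile_loglik  # local import, no cycle at load

        V = np.atleast_2d(np.asarray(profiles, dtype=float))
        f = np.atleast_1d(self.scaling(np.asarray(currents_mA, float)))
        means = f[:, None] * self.u_a_
        return gaussian_profile_loglik(
            V, means, self.Sigma_a_, self.T_eff_, self.quadform_scale
        )

    def score(self, profiles, currents_mA) -> float:
        return float(np.mean(self.log_likelihood(profiles, currents_mA)))

    def collapse(self, profiles, currents_mA):
        return collapse_profiles(profiles, currents_mA, self.I1_, self.I2_)
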