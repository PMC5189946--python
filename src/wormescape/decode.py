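"""Bayesian decoding of the applied laser current from escape behaviour.

The full observation model mixes the paused and active components with the
sigmoid state probabilities,

    P(v | I) = P(p|I) N(v; u_p, Sigma_p) + P(a|I) N(v; f(I) u_a, Sigma_a),

and Bayes' rule with a stimulus prior P(I) on a discrete current grid gives
the per-trial posterior P(I | v) and its expectation, the decoded
("perceived") stimulus level. Treated cohorts are always decoded with the
control-worm model, so differences in the decoded current reflect perception,
not model changes.

The Gaussian components use the effective number of independent time points
T in the (2 pi)^(T/2) normalisation together with the full profile-dimension
quadratic form, the convention under which the paused/active components are
compared; ``quadform_scale="T_over_D"`` instead rescales the quadratic form
by T/D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

from .active import ActiveResponseModel, fit_paused_template, scaling_function
from .pause import PauseCurrentModel, pause_probability
from .preprocessing import effective_independent_points

__all__ = [
    "StimulusPrior",
    "CurrentPosterior",
    "build_prior",
    "gaussian_profile_loglik",
    "mixture_loglik",
    "posterior_current",
    "posterior_by_bin",
    "EscapeResponseModel",
]


# ---------------------------------------------------------------------------
# Gaussian building block
# ---------------------------------------------------------------------------

def gaussian_profile_loglik(
    V: np.ndarray,
    means: np.ndarray,
    Sigma: np.ndarray,
    T_eff: float,
    quadform_scale: str = "none",
) -> np.ndarray:
    """log N(v; mean, Sigma) with the effective-T normalisation.

    ``V`` is (n, d), ``means`` broadcastable to (n, d). The log-density is
    -T/2 log(2 pi) - 1/2 log|Sigma| - 1/2 q(v), with q the full d-dimensional
    quadratic form (optionally rescaled by T/d).
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    d = V.shape[1]
    R = V - means
    cf = cho_factor(Sigma, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    q = np.sum(R * cho_solve(cf, R.T).T, axis=1)
    if quadform_scale == "T_over_D":
        q = q * (T_eff / d)
    elif quadform_scale != "none":
        raise ValueError(f"unknown quadform_scale {quadform_scale!r}")
    return -0.5 * T_eff * np.log(2.0 * np.pi) - 0.5 * logdet - 0.5 * q


# ---------------------------------------------------------------------------
# Stimulus prior
# ---------------------------------------------------------------------------

@dataclass
class StimulusPrior:
    """Discretised prior over the applied current."""

    grid_mA: np.ndarray
    density: np.ndarray  # per-mA density; sums (x step) to 1
    mode: str

    @property
    def step_mA(self) -> float:
        return float(self.grid_mA[1] - self.grid_mA[0])

    @property
    def log_density(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.density)


def build_prior(
    currents_mA: Sequence[float],
    mode: str = "empirical_kde",
    grid: Tuple[float, float, float] = (0.0, 200.0, 1.0),
) -> StimulusPrior:
    """Stimulus prior on the decoding grid.

    ``uniform`` is flat over the instrument range. ``empirical_kde`` is a
    Gaussian kernel density estimate (Silverman bandwidth) of the observed
    currents, boundary-reflected at both grid ends so mass pushed outside
    the range folds back in, then renormalised on the grid.
    """
    lo, hi, step = grid
    grid_mA = np.arange(lo, hi + step / 2, step)
    I = np.asarray(currents_mA, dtype=float)
    if I.size and (I.min() < lo or I.max() > hi):
        raise ValueError(f"currents outside the [{lo}, {hi}] mA grid")
    if mode == "uniform":
        density = np.full(grid_mA.size, 1.0 / (hi - lo))
    elif mode == "empirical_kde":
        if I.size < 2:
            raise ValueError("empirical prior needs at least 2 currents")
        kde = gaussian_kde(I, bw_method="silverman")
        density = kde(grid_mA) + kde(2 * lo - grid_mA) + kde(2 * hi - grid_mA)
    else:
        raise ValueError(f"unknown prior mode {mode!r}")
    density = density / (density.sum() * step)
    return StimulusPrior(grid_mA=grid_mA, density=density, mode=mode)


# ---------------------------------------------------------------------------
# Posterior containers
# ---------------------------------------------------------------------------

@dataclass
class CurrentPosterior:
    """P(I | v) on the current grid with its expectation (the decoded level)."""

    grid_mA: np.ndarray
    posterior: np.ndarray  # sums to 1

    @property
    def expectation_mA(self) -> float:
        return float(np.sum(self.grid_mA * self.posterior))


# ---------------------------------------------------------------------------
# Full worm-type model
# ---------------------------------------------------------------------------

class EscapeResponseModel(BaseEstimator):
    """Complete statistical model of one worm type's heat-evoked escape.

    ``fit(profiles, currents)`` classifies each model-window profile as
    active or paused (cutoff on the maximum reverse speed), fits the sigmoid
    pause current, the paused template, the scaled active template, the
    effective number of independent time points and the stimulus prior.
    ``predict`` then decodes the expected current for new profiles;
    ``predict_posterior`` returns the full posterior rows.
    """

    def __init__(
        self,
        active_cutoff_px_s: float = 10.0,
        n_restarts: int = 10,
        prior_mode: str = "empirical_kde",
        current_grid: Tuple[float, float, float] = (0.0, 200.0, 1.0),
        quadform_scale: str = "none",
        ridge_epsilon: float = 1e-6,
        window_duration_s: float = 2.3,
        subsample_hz: float = 12.0,
        random_state: Optional[int] = None,
    ):
        self.active_cutoff_px_s = active_cutoff_px_s
        self.n_restarts = n_restarts
        self.prior_mode = prior_mode
        self.current_grid = current_grid
        self.quadform_scale = quadform_scale
        self.ridge_epsilon = ridge_epsilon
        self.window_duration_s = window_duration_s
        self.subsample_hz = subsample_hz
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------
    def fit(self, profiles, currents_mA, states=None):
        V = np.atleast_2d(np.asarray(profiles, dtype=float))
        I = np.asarray(currents_mA, dtype=float)
        if V.shape[0] != I.size:
            raise ValueError("profiles and currents disagree in length")
        if states is None:
            max_rev = np.maximum(0.0, -V.min(axis=1))
            paused = max_rev <= self.active_cutoff_px_s
        else:
            paused = np.asarray(states) == "paused"

        self.paused_ = paused
        self.pause_ = PauseCurrentModel().fit(I, paused)
        self.u_p_, self.Sigma_p_ = fit_paused_template(V[paused], self.ridge_epsilon)
        self.T_eff_ = effective_independent_points(
            V, self.subsample_hz, self.window_duration_s
        )
        self.active_ = ActiveResponseModel(
            n_restarts=self.n_restarts,
            T_eff=self.T_eff_,
            ridge_epsilon=self.ridge_epsilon,
            quadform_scale=self.quadform_scale,
            random_state=self.random_state,
        ).fit(V[~paused], I[~paused])
        self.prior_ = build_prior(I, self.prior_mode, self.current_grid)
        self.n_trials_ = int(I.size)
        return self

    # -- likelihood --------------------------------------------------------
    def mixture_loglik(self, profiles, currents_mA) -> np.ndarray:
        """log P(v | I) of the two-state mixture, per (profile, current) pair.

        ``currents_mA`` may be a scalar, a per-profile vector, or a grid: the
        result has shape (n_profiles,) for the first two and
        (n_profiles, n_grid) when a grid is decoded against every profile.
        """
        V = np.atleast_2d(np.asarray(profiles, dtype=float))
        I = np.asarray(currents_mA, dtype=float)
        grid_mode = I.ndim == 1 and I.size != V.shape[0]
        if I.ndim == 0:
            I = np.full(V.shape[0], float(I))
        if grid_mode:
            ll = self._loglik_grid(V, I)
        else:
            ll = self._loglik_paired(V, I)
        return ll

    def _loglik_paired(self, V: np.ndarray, I: np.ndarray) -> np.ndarray:
        lp = gaussian_profile_loglik(
            V, self.u_p_, self.Sigma_p_, self.T_eff_, self.quadform_scale
        )
        f = np.atleast_1d(self.active_.scaling(I))
        la = gaussian_profile_loglik(
            V, f[:, None] * self.active_.u_a_, self.Sigma_a_, self.T_eff_,
            self.quadform_scale,
        )
        wp = np.atleast_1d(pause_probability(I, self.I0_mA_))
        with np.errstate(divide="ignore"):
            return logsumexp(
                np.stack([np.log(wp) + lp, np.log1p(-wp) + la]), axis=0
            )

    def _loglik_grid(self, V: np.ndarray, grid: np.ndarray) -> np.ndarray:
        """(n, g) mixture log-likelihood of every profile at every grid current.

        The active quadratic form is quadratic in f(I), so the grid sweep
        reuses three per-profile scalars instead of recomputing d-dimensional
        solves at every grid point.
        """
        d = V.shape[1]
        scale = (self.T_eff_ / d) if self.quadform_scale == "T_over_D" else 1.0
        const = -0.5 * self.T_eff_ * np.log(2.0 * np.pi)

        cf_p = cho_factor(self.Sigma_p_, lower=True)
        logdet_p = 2.0 * np.sum(np.log(np.diag(cf_p[0])))
        Rp = V - self.u_p_
        qp = np.sum(Rp * cho_solve(cf_p, Rp.T).T, axis=1)
        lp = const - 0.5 * logdet_p - 0.5 * scale * qp  # (n,)

        cf_a = cho_factor(self.Sigma_a_, lower=True)
        logdet_a = 2.0 * np.sum(np.log(np.diag(cf_a[0])))
        u = self.active_.u_a_
        Au = cho_solve(cf_a, u)
        a2 = float(u @ Au)  # u' S^-1 u
        a1 = V @ Au  # (n,)
        a0 = np.sum(V * cho_solve(cf_a, V.T).T, axis=1)  # (n,)
        f = np.atleast_1d(self.active_.scaling(grid))  # (g,)
        qa = a0[:, None] - 2.0 * np.outer(a1, f) + a2 * f[None, :] ** 2
        la = const - 0.5 * logdet_a - 0.5 * scale * qa  # (n, g)

        wp = np.atleast_1d(pause_probability(grid, self.I0_mA_))  # (g,)
        with np.errstate(divide="ignore"):
            stacked = np.stack(
                [np.log(wp)[None, :] + lp[:, None], np.log1p(-wp)[None, :] + la]
            )
        return logsumexp(stacked, axis=0)

    # -- decoding ----------------------------------------------------------
    def predict_posterior(self, profiles) -> np.ndarray:
        """Rows of P(I | v) on the current grid, one per profile."""
        V = np.atleast_2d(np.asarray(profiles, dtype=float))
        grid = self.prior_.grid_mA
        log_post = self._loglik_grid(V, grid) + self.prior_.log_density[None, :]
        log_post -= logsumexp(log_post, axis=1, keepdims=True)
        post = np.exp(log_post)
        if not np.all(np.isfinite(post.sum(axis=1))):
            raise FloatingPointError("posterior normalisation underflowed")
        return post

    def predict(self, profiles) -> np.ndarray:
        """Expected decoded current (mA) per profile."""
        post = self.predict_posterior(profiles)
        return post @ self.prior_.grid_mA

    def score(self, profiles, currents_mA) -> float:
        return float(np.mean(self.mixture_loglik(profiles, currents_mA)))

    # -- conveniences ------------------------------------------------------
    @property
    def I0_mA_(self) -> float:
        return self.pause_.I0_mA_

    @property
    def Sigma_a_(self) -> np.ndarray:
        return self.active_.Sigma_a_

    @property
    def grid_mA(self) -> np.ndarray:
        return self.prior_.grid_mA


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def mixture_loglik(profile, current_mA, model: EscapeResponseModel):
    """log P(v | I) of one profile at one current under a fitted model."""
    out = model.mixture_loglik(np.atleast_2d(profile), float(current_mA))
    return float(out[0])


def posterior_current(profile, model: EscapeResponseModel) -> CurrentPosterior:
    """Posterior over the current grid for a single profile."""
    post = model.predict_posterior(np.atleast_2d(profile))[0]
    return CurrentPosterior(grid_mA=model.grid_mA, posterior=post)


def posterior_by_bin(
    profiles, currents_mA, model: EscapeResponseModel, bin_ids
) -> Tuple[np.ndarray, np.ndarray]:
    """Average per-trial posteriors within each applied-current bin.

    Returns (bin_posteriors, counts); rows of empty bins are NaN.
    """
    post = model.predict_posterior(profiles)
    bin_ids = np.asarray(bin_ids)
    n_bins = int(bin_ids.max()) + 1 if bin_ids.size else 0
    out = np.full((n_bins, post.shape[1]), np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = bin_ids == b
        counts[b] = mask.sum()
        if counts[b]:
            out[b] = post[mask].mean(axis=0)
    return out, counts
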