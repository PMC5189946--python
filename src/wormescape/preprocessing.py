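"""Smoothing, subsampling, windowing and active/paused classification.

Raw 60 Hz signed velocity traces are smoothed with a truncated Gaussian
kernel (one-sided and renormalised near the edges), subsampled at 12 Hz and
windowed to the modelling interval. A trial is *active* when its maximum
reverse speed in the post-stimulus window exceeds the cutoff (10 pixels/s by
default), otherwise *paused*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .config import RunConfig
from .datasets import Cohort, Trial

__all__ = [
    "ProcessedTrial",
    "smooth_velocity",
    "subsample_and_window",
    "classify_state",
    "effective_independent_points",
    "VelocityPreprocessor",
    "process_cohort",
]


def _gaussian_kernel(filter_width_s: float, raw_hz: float) -> np.ndarray:
    # sigma = width / 4, truncated at +/- 2 sigma, so the support equals the
    # nominal filter width.
    sigma_s = filter_width_s / 4.0
    half = int(round(2.0 * sigma_s * raw_hz))
    half = max(half, 1)
    t = np.arange(-half, half + 1) / raw_hz
    return np.exp(-0.5 * (t / sigma_s) ** 2)


def smooth_velocity(
    velocity_raw: Sequence[float], filter_width_s: float, raw_hz: float = 60.0
) -> np.ndarray:
    """Edge-aware Gaussian smoothing of a raw velocity trace.

    At every output sample the truncated kernel is restricted to in-range
    input samples and renormalised to unit mass, which reduces to a one-sided
    Gaussian at the trace edges and preserves constants everywhere.
    """
    v = np.asarray(velocity_raw, dtype=float)
    if v.ndim != 1:
        raise ValueError("velocity trace must be 1-D")
    bad = np.flatnonzero(~np.isfinite(v))
    if bad.size:
        raise ValueError(f"non-finite velocity samples at indices {bad.tolist()}")
    if filter_width_s <= 0:
        raise ValueError("filter_width_s must be positive")
    kernel = _gaussian_kernel(filter_width_s, raw_hz)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def subsample_and_window(
    smoothed: Sequence[float],
    raw_hz: float,
    subsample_hz: float,
    window_s: Tuple[float, float],
) -> np.ndarray:
    """Samples at t = lo + k/subsample_hz for all k >= 0 with t <= hi.

    The default 60 -> 12 Hz stride is 5 raw samples; the [1.0, 4.0] s window
    yields 37 points and the [1.0, 3.3] s modelling window 28 (last grid
    point t = 3.25 s).
    """
    v = np.asarray(smoothed, dtype=float)
    stride_f = raw_hz / subsample_hz
    stride = int(round(stride_f))
    if abs(stride_f - stride) > 1e-9:
        raise ValueError("raw_hz must be an integer multiple of subsample_hz")
    lo, hi = window_s
    i0 = lo * raw_hz
    if abs(i0 - round(i0)) > 1e-6:
        raise ValueError("window start does not align with the raw sampling grid")
    i0 = int(round(i0))
    # number of subsample steps with lo + k / subsample_hz <= hi (tolerant of
    # floating-point representation of the endpoint)
    k_max = int(np.floor((hi - lo) * subsample_hz + 1e-9))
    idx = i0 + stride * np.arange(k_max + 1)
    if i0 < 0 or idx[-1] >= v.size:
        raise ValueError(
            f"window {window_s} outside the trace (length {v.size} at {raw_hz} Hz)"
        )
    return v[idx]


def classify_state(
    profile: Sequence[float], cutoff_px_s: float = 10.0
) -> Tuple[str, float]:
    """Return ("active"|"paused", max_reverse_speed) for a windowed profile.

    The maximum reverse speed is the magnitude of the most negative velocity
    (0 if the worm never reverses); a trial is active iff it is *strictly*
    greater than the cutoff.
    """
    p = np.asarray(profile, dtype=float)
    if p.size == 0:
        raise ValueError("empty profile")
    max_reverse = max(0.0, -float(p.min()))
    state = "active" if max_reverse > cutoff_px_s else "paused"
    return state, max_reverse


def effective_independent_points(
    profiles: np.ndarray,
    subsample_hz: float,
    duration_s: Optional[float] = None,
) -> float:
    """Effective number of independent time points T in a set of profiles.

    T = (window duration) / tau, where tau is the pooled velocity correlation
    time: the first lag at which the empirical autocorrelation of the
    mean-subtracted profiles drops below 1/e (linear interpolation between
    integer lags), floored at one subsample interval.
    """
    V = np.atleast_2d(np.asarray(profiles, dtype=float))
    n, p = V.shape
    if n < 2:
        raise ValueError("need at least 2 profiles")
    R = V - V.mean(axis=0, keepdims=True)
    denom = float(np.sum(R * R))
    if denom <= 0:
        raise ValueError("zero-variance profiles: correlation time undefined")
    acf = np.empty(p)
    acf[0] = 1.0
    for lag in range(1, p):
        num = float(np.sum(R[:, :-lag] * R[:, lag:]))
        cnt = n * (p - lag)
        acf[lag] = (num / cnt) / (denom / (n * p))
    thresh = 1.0 / np.e
    below = np.flatnonzero(acf < thresh)
    dt = 1.0 / subsample_hz
    if below.size == 0:
        tau = (p - 1) * dt  # never decorrelates within the window
    else:
        k = int(below[0])
        a, b = acf[k - 1], acf[k]
        frac = (a - thresh) / (a - b) if a != b else 0.0
        tau = (k - 1 + frac) * dt
    tau = max(tau, dt)
    if duration_s is None:
        duration_s = p / subsample_hz
    return duration_s / tau


@dataclass
class ProcessedTrial:
    """Smoothed, subsampled, windowed view of one trial."""

    trial_id: str
    worm_type: str
    applied_current_mA: float
    state: str  # "active" | "paused"
    max_reverse_speed_px_s: float
    profile_full: np.ndarray  # 12 Hz on [1.0, 4.0] s: 37 points
    profile_model: np.ndarray  # 12 Hz on [1.0, 3.3] s: 28 points


class VelocityPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer from raw 60 Hz traces to model-window velocity profiles.

    ``transform`` maps an (n_trials, n_samples) matrix of raw traces to the
    (n_trials, 28) matrix of smoothed 12 Hz profiles on the modelling window.
    The transformer is stateless; ``fit`` only validates parameters.
    """

    def __init__(
        self,
        filter_width_s: float = 0.5,
        raw_hz: float = 60.0,
        subsample_hz: float = 12.0,
        model_window_s: Tuple[float, float] = (1.0, 3.3),
        full_window_s: Tuple[float, float] = (1.0, 4.0),
        active_cutoff_px_s: float = 10.0,
    ):
        self.filter_width_s = filter_width_s
        self.raw_hz = raw_hz
        self.subsample_hz = subsample_hz
        self.model_window_s = model_window_s
        self.full_window_s = full_window_s
        self.active_cutoff_px_s = active_cutoff_px_s

    def fit(self, X=None, y=None):
        _gaussian_kernel(self.filter_width_s, self.raw_hz)  # validates width
        return self

    def _window(self, X: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        rows = [
            subsample_and_window(
                smooth_velocity(row, self.filter_width_s, self.raw_hz),
                self.raw_hz,
                self.subsample_hz,
                window,
            )
            for row in X
        ]
        return np.vstack(rows)

    def transform(self, X) -> np.ndarray:
        return self._window(X, self.model_window_s)

    def transform_full(self, X) -> np.ndarray:
        return self._window(X, self.full_window_s)

    def classify(self, X) -> Tuple[np.ndarray, np.ndarray]:
        """States and max reverse speeds from the model-window profiles."""
        P = self.transform(X)
        max_rev = np.maximum(0.0, -P.min(axis=1))
        states = np.where(max_rev > self.active_cutoff_px_s, "active", "paused")
        return states, max_rev

    @property
    def model_grid_s(self) -> np.ndarray:
        lo, hi = self.model_window_s
        k = int(np.floor((hi - lo) * self.subsample_hz + 1e-9))
        return lo + np.arange(k + 1) / self.subsample_hz


def process_cohort(cohort: Cohort, config: Optional[RunConfig] = None) -> List[ProcessedTrial]:
    """Apply the full preprocessing path to every trial of a cohort."""
    config = config or RunConfig()
    pre = VelocityPreprocessor(
        filter_width_s=config.filter_width_s,
        raw_hz=config.raw_hz,
        subsample_hz=config.subsample_hz,
        model_window_s=config.model_window_s,
        full_window_s=config.full_window_s,
        active_cutoff_px_s=config.active_cutoff_px_s,
    )
    out: List[ProcessedTrial] = []
    for trial in cohort.trials:
        smoothed = smooth_velocity(trial.velocity_raw, config.filter_width_s, config.raw_hz)
        full = subsample_and_window(
            smoothed, config.raw_hz, config.subsample_hz, config.full_window_s
        )
        model = subsample_and_window(
            smoothed, config.raw_hz, config.subsample_hz, config.model_window_s
        )
        state, max_rev = classify_state(model, config.active_cutoff_px_s)
        out.append(
            ProcessedTrial(
                trial_id=trial.trial_id,
                worm_type=trial.worm_type,
                applied_current_mA=trial.applied_current_mA,
                state=state,
                max_reverse_speed_px_s=max_rev,
                profile_full=full,
                profile_model=model,
            )
        )
    return out
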