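"""Generative simulator of heat-evoked escape trials.

Each simulated trial draws a laser current uniformly on [0, 200] mA, a
paused/active state from the sigmoid pause model, and then a 60 Hz signed
velocity trace: a pre-stimulus forward baseline, plus (active trials) the
current-scaled canonical reversal template or (paused trials) a decaying
stop, plus stationary Gaussian noise with exponential temporal covariance
sigma^2 exp(-|dt| / corr_time).

The canonical active template is an invented smooth fixture -- a positive
baseline, a Gaussian-shaped reversal lobe with minimum normalised to -1 on
the 28-point modelling grid, and a sigmoid recovery -- whose timing
qualitatively matches real escapes (reversal minimum near t ~ 1.8 s). The
published per-genotype scalar parameters (pause currents, scaling
parameters, the mutant's one-frame response lag and the forward-speed
statistics) are available as presets; the template *shape* itself is not a
measured quantity.

The template returned by :func:`canonical_template` is the smoothed,
subsampled view of the underlying continuous curve under the standard
preprocessing, so that a noise-free simulated trace processed through the
pipeline reproduces f(I) x template exactly (the smoothing is linear).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .active import scaling_function
from .datasets import Cohort, Trial
from .pause import pause_probability
from .preprocessing import smooth_velocity, subsample_and_window

__all__ = [
    "TemplateShape",
    "GenotypeSpec",
    "SimulatedDataset",
    "canonical_template",
    "simulate_cohort",
    "simulate_dataset",
    "simulate_active_profiles",
    "paper_preset",
    "frame_lag_ms",
]


@dataclass(frozen=True)
class TemplateShape:
    """Shape parameters of the canonical active escape (normalised units)."""

    baseline_rel: float = 0.12  # forward bias relative to reversal depth
    reversal_depth_rel: float = 1.0
    reversal_center_s: float = 1.8  # on the trial clock (stimulus at 1 s)
    reversal_width_s: float = 0.35
    recovery_rel: float = 0.45  # post-reversal forward recovery, per unit depth
    recovery_rise_s: float = 0.3
    lag_frames: int = 0  # whole 12 Hz frames of response delay


@dataclass(frozen=True)
class GenotypeSpec:
    """Everything needed to simulate one worm type."""

    label: str
    I0_mA: float
    I1: float
    I2: float  # +inf allowed: linear scaling
    template: TemplateShape = field(default_factory=TemplateShape)
    paused_decay_s: float = 0.4
    noise_sigma_px_s: float = 5.0
    noise_corr_time_s: float = 0.2
    forward_mean_px_s: float = 13.0
    forward_sd_px_s: float = 9.0

    def __post_init__(self):
        if not self.I0_mA > 0:
            raise ValueError("I0_mA must be positive")
        if not self.noise_sigma_px_s > 0:
            raise ValueError("noise sigma must be positive")
        if self.noise_corr_time_s < 1.0 / 60.0:
            raise ValueError("corr_time must be at least one raw frame")


@dataclass
class SimulatedDataset:
    """Cohorts plus the generating truth for recovery tests."""

    cohorts: List[Cohort]
    truth: pd.DataFrame  # per-trial latent state, f(I), forward speed
    specs: Dict[str, GenotypeSpec]
    seed: int


def frame_lag_ms(lag_frames: int, subsample_hz: float = 12.0) -> int:
    """Duration of a whole-frame response lag in milliseconds (rounded)."""
    return int(round(lag_frames * 1000.0 / subsample_hz))


def _shape_curve(t: np.ndarray, sh: TemplateShape, onset_s: float = 1.0) -> np.ndarray:
    """Continuous template curve on the trial clock (unnormalised).

    A constant forward bias plus, scaled by the reversal depth, a negative
    Gaussian reversal lobe and a sigmoid recovery toward forward motion; a
    zero-depth shape is therefore exactly flat. ``lag_frames`` shifts the
    whole response rightward in whole 12 Hz frames.
    """
    tl = t - sh.lag_frames / 12.0
    lobe = np.exp(-0.5 * ((tl - sh.reversal_center_s) / sh.reversal_width_s) ** 2)
    rec_center = sh.reversal_center_s + 3.0 * sh.reversal_width_s
    recovery = sh.recovery_rel / (1.0 + np.exp(-(tl - rec_center) / sh.recovery_rise_s))
    return sh.baseline_rel + sh.reversal_depth_rel * (recovery - lobe)


def _canonical_template_with_norm(
    spec: GenotypeSpec,
    raw_hz: float = 60.0,
    duration_s: float = 15.0,
    onset_s: float = 1.0,
    filter_width_s: float = 0.5,
    subsample_hz: float = 12.0,
    model_window_s: Tuple[float, float] = (1.0, 3.3),
) -> Tuple[np.ndarray, float]:
    lo, hi = model_window_s
    if not (lo <= spec.template.reversal_center_s + spec.template.lag_frames / 12.0 <= hi):
        raise ValueError(
            f"reversal_center_s={spec.template.reversal_center_s} (after lag) "
            f"outside the model window {model_window_s}"
        )
    t = np.arange(int(round(duration_s * raw_hz))) / raw_hz
    g = _shape_curve(t, spec.template, onset_s)
    gs = smooth_velocity(g, filter_width_s, raw_hz)
    prof = subsample_and_window(gs, raw_hz, subsample_hz, model_window_s)
    m = float(prof.min())
    if m >= 0:  # degenerate (e.g. zero reversal depth): nothing to normalise by
        return prof, 1.0
    return prof / abs(m), abs(m)


def canonical_template(spec: GenotypeSpec, **kwargs) -> np.ndarray:
    """Unit-normalised active template on the 28-point modelling grid.

    The minimum over the grid is exactly -1 (unless the shape has no
    reversal, in which case the flat curve is returned as-is).
    """
    template, _ = _canonical_template_with_norm(spec, **kwargs)
    return template


def _ou_noise(
    rng: np.random.Generator,
    n_trials: int,
    n_samples: int,
    sigma: float,
    corr_time_s: float,
    rate_hz: float,
) -> np.ndarray:
    """Stationary Gaussian process with covariance sigma^2 exp(-|dt|/tau)."""
    rho = np.exp(-1.0 / (rate_hz * corr_time_s))
    eps = rng.standard_normal((n_trials, n_samples))
    w = eps * (sigma * np.sqrt(1.0 - rho**2))
    w[:, 0] = eps[:, 0] * sigma  # stationary start
    return lfilter([1.0], [1.0, -rho], w, axis=1)


def simulate_cohort(
    spec: GenotypeSpec,
    n_trials: int,
    seed: int = 0,
    current_law: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    raw_hz: float = 60.0,
    duration_s: float = 15.0,
    onset_s: float = 1.0,
    filter_width_s: float = 0.5,
    subsample_hz: float = 12.0,
    model_window_s: Tuple[float, float] = (1.0, 3.3),
    id_prefix: Optional[str] = None,
) -> Tuple[Cohort, pd.DataFrame]:
    """Simulate raw 60 Hz trials; returns (cohort, per-trial truth table)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    I = (
        current_law(rng, n_trials)
        if current_law is not None
        else rng.uniform(0.0, 200.0, n_trials)
    )
    paused = rng.random(n_trials) < pause_probability(I, spec.I0_mA)
    v_fwd = rng.normal(spec.forward_mean_px_s, spec.forward_sd_px_s, n_trials)
    f_vals = np.atleast_1d(scaling_function(I, spec.I1, spec.I2))

    n_samples = int(round(duration_s * raw_hz))
    t = np.arange(n_samples) / raw_hz
    _, norm = _canonical_template_with_norm(
        spec, raw_hz, duration_s, onset_s, filter_width_s, subsample_hz, model_window_s
    )
    g = _shape_curve(t, spec.template, onset_s) / norm  # active response, 60 Hz
    post = np.maximum(t - onset_s, 0.0)
    fwd_env_active = np.where(t < onset_s, 1.0, 0.0)  # baseline only pre-stimulus
    fwd_env_paused = np.where(
        t < onset_s, 1.0, np.exp(-post / spec.paused_decay_s)
    )  # paused worms coast to a stop

    noise = _ou_noise(
        rng, n_trials, n_samples, spec.noise_sigma_px_s, spec.noise_corr_time_s, raw_hz
    )
    V = np.empty((n_trials, n_samples))
    for i in range(n_trials):
        if paused[i]:
            V[i] = v_fwd[i] * fwd_env_paused
        else:
            V[i] = v_fwd[i] * fwd_env_active + f_vals[i] * g
    V += noise

    prefix = id_prefix or spec.label
    trials = [
        Trial(
            trial_id=f"{prefix}-{i:05d}",
            worm_type=spec.label,
            applied_current_mA=float(I[i]),
            velocity_raw=V[i],
            stimulus_onset_s=onset_s,
        )
        for i in range(n_trials)
    ]
    truth = pd.DataFrame(
        {
            "trial_id": [tr.trial_id for tr in trials],
            "applied_current_mA": I,
            "paused": paused,
            "f_I": f_vals,
            "forward_speed_px_s": v_fwd,
        }
    )
    return Cohort(worm_type=spec.label, trials=trials), truth


def simulate_dataset(
    specs: Dict[str, GenotypeSpec] | List[GenotypeSpec],
    n_per_cohort: int | Dict[str, int],
    seed: int = 0,
    **kwargs,
) -> SimulatedDataset:
    """Simulate several cohorts with per-cohort seeds spawned from ``seed``."""
    if isinstance(specs, dict):
        specs = list(specs.values())
    seeds = np.random.SeedSequence(seed).spawn(len(specs))
    cohorts, truths = [], []
    for spec, ss in zip(specs, seeds):
        n = n_per_cohort[spec.label] if isinstance(n_per_cohort, dict) else n_per_cohort
        sub_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        cohort, truth = simulate_cohort(spec, n, seed=sub_seed, **kwargs)
        truth.insert(1, "worm_type", spec.label)
        cohorts.append(cohort)
        truths.append(truth)
    return SimulatedDataset(
        cohorts=cohorts,
        truth=pd.concat(truths, ignore_index=True),
        specs={s.label: s for s in specs},
        seed=seed,
    )


def simulate_active_profiles(
    n_trials: int,
    I1: float,
    I2: float,
    template: np.ndarray,
    noise_sigma_px_s: float = 2.0,
    noise_corr_time_s: float = 0.2,
    seed: int = 0,
    subsample_hz: float = 12.0,
    current_lo_mA: float = 0.0,
    current_hi_mA: float = 200.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Directly simulate 12 Hz model-window profiles v = f(I) u + noise.

    Bypasses the raw-trace path; used for scaling-parameter recovery
    experiments where the template is known exactly. Returns (profiles,
    currents).
    """
    rng = np.random.default_rng(seed)
    template = np.asarray(template, dtype=float)
    I = rng.uniform(current_lo_mA, current_hi_mA, n_trials)
    f = np.atleast_1d(scaling_function(I, I1, I2))
    noise = _ou_noise(
        rng, n_trials, template.size, noise_sigma_px_s, noise_corr_time_s, subsample_hz
    )
    return f[:, None] * template + noise, I


# ---------------------------------------------------------------------------
# Published per-genotype parameters
# ---------------------------------------------------------------------------

_PRESETS: Dict[str, GenotypeSpec] = {
    "control": GenotypeSpec(
        label="control",
        I0_mA=25.9,
        I1=-4.5,
        I2=45.0,
        forward_mean_px_s=13.0,
        forward_sd_px_s=9.0,
    ),
    "ibuprofen": GenotypeSpec(
        label="ibuprofen",
        I0_mA=26.6,
        I1=-4.5,
        I2=12.0,
        forward_mean_px_s=9.0,
        forward_sd_px_s=7.0,
    ),
    "mutant": GenotypeSpec(
        label="mutant",
        I0_mA=51.6,
        I1=66.5,
        I2=np.inf,
        template=TemplateShape(lag_frames=1),
        forward_mean_px_s=13.0,
        forward_sd_px_s=10.0,
    ),
}


def paper_preset(label: str) -> GenotypeSpec:
    """Per-genotype simulator parameters at their published values.

    control: I0 = 25.9 mA, I1 = -4.5, I2 = 45.0; ibuprofen: I0 = 26.6 mA,
    I1 = -4.5, I2 = 12.0; mutant: I0 = 51.6 mA, I1 = 66.5, I2 = +inf with a
    one-frame (83 ms at 12 Hz) response lag. Forward-speed statistics
    13 +/- 9, 9 +/- 7 and 13 +/- 10 pixels/s respectively.
    """
    try:
        return _PRESETS[label]
    except KeyError:
        raise ValueError(
            f"unknown preset {label!r}; choose from {sorted(_PRESETS)}"
        ) from None
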