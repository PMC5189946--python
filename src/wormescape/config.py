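"""Run configuration shared across the analysis pipeline.

All times are in seconds, laser currents in mA and velocities in pixels/s;
units are fixed here at the boundary so the numerical code is unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Tuple

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved parameters of one analysis run.

    Parameters
    ----------
    filter_width_s : total width of the Gaussian smoothing filter (the kernel
        is truncated at +/- 2 sigma with sigma = filter_width_s / 4).
    subsample_hz : rate at which smoothed traces are subsampled for modelling.
    raw_hz : acquisition rate of the velocity traces.
    model_window_s : time window (since trial start) used for model fitting;
        the stimulus is applied at t = 1 s.
    full_window_s : wider window retained for inspection (37 points at 12 Hz).
    active_cutoff_px_s : maximum-reverse-speed threshold separating active
        escapes from paused trials.
    n_bins : number of equal-count current bins used for presentation,
        variance decomposition and effect estimation.
    current_grid : (lo, hi, step) of the discrete current grid for decoding.
    bootstrap_B : number of bootstrap resamples for error bars.
    n_restarts : random initialisations of the scaling-parameter optimiser.
    prior_mode : "empirical_kde" or "uniform" stimulus prior.
    quadform_scale : "none" keeps the Gaussian quadratic form at its full
        dimension; "T_over_D" rescales it by T_eff / n_points.
    ridge_epsilon : relative ridge added to ill-conditioned covariances.
    """

    filter_width_s: float = 0.5
    subsample_hz: float = 12.0
    raw_hz: float = 60.0
    duration_s: float = 15.0
    stimulus_onset_s: float = 1.0
    model_window_s: Tuple[float, float] = (1.0, 3.3)
    full_window_s: Tuple[float, float] = (1.0, 4.0)
    active_cutoff_px_s: float = 10.0
    n_bins: int = 5
    current_grid: Tuple[float, float, float] = (0.0, 200.0, 1.0)
    bootstrap_B: int = 1000
    n_restarts: int = 10
    rng_seed: int = 0
    prior_mode: str = "empirical_kde"
    quadform_scale: str = "none"
    ridge_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.filter_width_s <= 0:
            raise ValueError("filter_width_s must be positive")
        stride = self.raw_hz / self.subsample_hz
        if abs(stride - round(stride)) > 1e-9:
            raise ValueError(
                f"raw_hz ({self.raw_hz}) must be an integer multiple of "
                f"subsample_hz ({self.subsample_hz})"
            )
        for name in ("model_window_s", "full_window_s"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= self.duration_s):
                raise ValueError(f"{name}={lo, hi} outside trial duration")
        if self.prior_mode not in ("empirical_kde", "uniform"):
            raise ValueError(f"unknown prior_mode {self.prior_mode!r}")
        if self.quadform_scale not in ("none", "T_over_D"):
            raise ValueError(f"unknown quadform_scale {self.quadform_scale!r}")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    # -- convenience -------------------------------------------------------
    @property
    def stride(self) -> int:
        return int(round(self.raw_hz / self.subsample_hz))

    @property
    def n_raw_samples(self) -> int:
        return int(round(self.duration_s * self.raw_hz))

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = asdict(self)
        for key in ("model_window_s", "full_window_s", "current_grid"):
            doc[key] = list(doc[key])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("model_window_s", "full_window_s", "current_grid"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)
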