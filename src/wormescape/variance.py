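"""Per-time-point variance decomposition of active escape responses.

The total across-trial variance at each time point splits exactly (with
population, 1/n, variances) into the current-driven part -- the
count-weighted variance of current-bin means -- and the individual part,
the mean within-bin variance:

    sigma2_total = sigma2_I + sigma2_ind.

The current-driven ("explainable") part further splits into what the
scaled-template model captures and a residual,

    sigma2_I = sigma2_m + sigma2_res,

where sigma2_res is the count-weighted squared deviation of the empirical
bin means from the model prediction f(I_bin_mean) * u_a, and sigma2_m is
obtained by subtraction, clipped at zero (clipping is reported). This is
the operational definition under which the second identity holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

__all__ = ["VarianceDecomposition", "decompose_variance", "explainable_fraction"]


@dataclass
class VarianceDecomposition:
    time_grid_s: Optional[np.ndarray]
    sigma2_total: np.ndarray
    sigma2_I: np.ndarray
    sigma2_ind: np.ndarray
    sigma2_m: Optional[np.ndarray]
    sigma2_res: Optional[np.ndarray]
    n_bins: int
    bin_counts: np.ndarray
    clipped: Optional[np.ndarray] = None  # where sigma2_m hit the 0 floor


def decompose_variance(
    profiles: np.ndarray,
    currents_mA: np.ndarray,
    bin_ids: np.ndarray,
    model_prediction: Optional[Callable[[float], np.ndarray]] = None,
    time_grid_s: Optional[np.ndarray] = None,
) -> VarianceDecomposition:
    """Decompose per-time-point response variance over current bins.

    ``model_prediction`` maps a bin's mean current to its predicted profile
    (for a fitted scaled-template model: ``lambda I: f(I) * u_a``); when
    given, the model/residual split of the explainable variance is also
    computed.
    """
    V = np.atleast_2d(np.asarray(profiles, dtype=float))
    I = np.asarray(currents_mA, dtype=float)
    bin_ids = np.asarray(bin_ids)
    n, d = V.shape
    n_bins = int(bin_ids.max()) + 1
    counts = np.bincount(bin_ids, minlength=n_bins)
    if np.any(counts == 0):
        raise ValueError(f"empty current bin(s): {np.flatnonzero(counts == 0).tolist()}")

    grand = V.mean(axis=0)
    sigma2_total = np.mean((V - grand) ** 2, axis=0)

    w = counts / n
    bin_means = np.vstack([V[bin_ids == b].mean(axis=0) for b in range(n_bins)])
    sigma2_I = np.sum(w[:, None] * (bin_means - grand) ** 2, axis=0)
    within = np.vstack(
        [np.mean((V[bin_ids == b] - bin_means[b]) ** 2, axis=0) for b in range(n_bins)]
    )
    sigma2_ind = np.sum(w[:, None] * within, axis=0)

    sigma2_m = sigma2_res = clipped = None
    if model_prediction is not None:
        preds = np.vstack(
            [model_prediction(float(I[bin_ids == b].mean())) for b in range(n_bins)]
        )
        sigma2_res = np.sum(w[:, None] * (bin_means - preds) ** 2, axis=0)
        raw_m = sigma2_I - sigma2_res
        clipped = raw_m < 0
        sigma2_m = np.where(clipped, 0.0, raw_m)

    return VarianceDecomposition(
        time_grid_s=None if time_grid_s is None else np.asarray(time_grid_s, float),
        sigma2_total=sigma2_total,
        sigma2_I=sigma2_I,
        sigma2_ind=sigma2_ind,
        sigma2_m=sigma2_m,
        sigma2_res=sigma2_res,
        n_bins=n_bins,
        bin_counts=counts,
        clipped=clipped,
    )


def explainable_fraction(
    dec: VarianceDecomposition,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """(sigma2_I / sigma2_total, sigma2_res / sigma2_I) over the time grid.

    Ratios are clipped to [0, 1]; points with a zero denominator are NaN.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_I = np.where(
            dec.sigma2_total > 0, dec.sigma2_I / dec.sigma2_total, np.nan
        )
        frac_res = None
        if dec.sigma2_res is not None:
            frac_res = np.where(
                dec.sigma2_I > 0, dec.sigma2_res / dec.sigma2_I, np.nan
            )
            frac_res = np.clip(frac_res, 0.0, 1.0)
    return np.clip(frac_I, 0.0, 1.0), frac_res
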