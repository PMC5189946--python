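"""Perceived-stimulus reduction between cohorts, bootstrap errors, power.

Every trial -- control or treated -- is decoded with the *control* model.
Each control trial is paired with the treated trial of nearest applied
current; the average decoded-current difference within each equal-count
control-current bin is the perceived stimulus reduction Delta I for that
bin. Errors come from bootstrapping the whole pipeline: both cohorts are
resampled with replacement, the control model is refitted, trials are
re-paired and Delta I recomputed; the SD over replicates gives the Z score.
The power curve repeats this while subsampling n treated trials from one
stimulus bin, tracing how significance grows with cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.base import clone

from .binning import bin_by_edges, quantile_bins
from .decode import EscapeResponseModel

__all__ = [
    "EffectEstimate",
    "PowerCurve",
    "match_pairs",
    "delta_I",
    "bootstrap_effect",
    "power_curve",
]


@dataclass
class EffectEstimate:
    """Per-bin perceived-stimulus reduction with bootstrap uncertainty."""

    bin_centers_mA: np.ndarray
    delta_I_mA: np.ndarray
    n_pairs: np.ndarray
    mean_current_mismatch_mA: float
    overall_delta_I_mA: float
    delta_sd_mA: Optional[np.ndarray] = None
    z_score: Optional[np.ndarray] = None
    overall_sd_mA: Optional[float] = None
    overall_z: Optional[float] = None
    B: Optional[int] = None
    n_fit_failures: int = 0


@dataclass
class PowerCurve:
    """Z score of the perceived-stimulus reduction vs. treated sample size."""

    n_values: np.ndarray
    delta_of_n: np.ndarray
    sd_of_n: np.ndarray
    z_of_n: np.ndarray
    B: int
    bin_index: int
    bin_center_mA: float


def match_pairs(
    control_currents: Sequence[float], treated_currents: Sequence[float]
) -> Tuple[np.ndarray, float]:
    """Nearest-applied-current pairing j(i) of treated to control trials.

    Treated trials may serve several control trials; ties break to the
    lowest treated index. Returns (indices, mean |current mismatch| in mA).
    """
    Ic = np.asarray(control_currents, dtype=float)
    It = np.asarray(treated_currents, dtype=float)
    if It.size == 0:
        raise ValueError("treated cohort is empty")
    # argmin returns the first (lowest-index) minimiser, the documented tie-break
    j = np.abs(Ic[:, None] - It[None, :]).argmin(axis=1)
    mismatch = float(np.mean(np.abs(Ic - It[j]))) if Ic.size else 0.0
    return j, mismatch


def _binned_deltas(
    diffs: np.ndarray, control_currents: np.ndarray, edges: np.ndarray, n_bins: int
) -> Tuple[np.ndarray, np.ndarray]:
    ids = bin_by_edges(control_currents, edges)
    out = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = ids == b
        counts[b] = mask.sum()
        if counts[b]:
            out[b] = diffs[mask].mean()
    return out, counts


def delta_I(
    decoded_control_mA: Sequence[float],
    control_currents: Sequence[float],
    decoded_treated_mA: Sequence[float],
    treated_currents: Sequence[float],
    n_bins: int = 5,
    edges: Optional[np.ndarray] = None,
) -> EffectEstimate:
    """Per-bin mean decoded-current difference (control - matched treated).

    Bins are equal-count quantile bins of the control currents unless
    precomputed ``edges`` are supplied (as during bootstrap replicates,
    which keep the full-data bins).
    """
    dc = np.asarray(decoded_control_mA, dtype=float)
    dt = np.asarray(decoded_treated_mA, dtype=float)
    Ic = np.asarray(control_currents, dtype=float)
    It = np.asarray(treated_currents, dtype=float)
    j, mismatch = match_pairs(Ic, It)
    diffs = dc - dt[j]
    if edges is None:
        _, edges = quantile_bins(Ic, n_bins)
    deltas, counts = _binned_deltas(diffs, Ic, np.asarray(edges), n_bins)
    ids = bin_by_edges(Ic, edges)
    centers = np.array(
        [Ic[ids == b].mean() if (ids == b).any() else np.nan for b in range(n_bins)]
    )
    return EffectEstimate(
        bin_centers_mA=centers,
        delta_I_mA=deltas,
        n_pairs=counts,
        mean_current_mismatch_mA=mismatch,
        overall_delta_I_mA=float(diffs.mean()),
    )


def _ensure_fitted(
    model: EscapeResponseModel, V: np.ndarray, I: np.ndarray
) -> EscapeResponseModel:
    if not hasattr(model, "pause_"):
        model = clone(model).fit(V, I)
    return model


def _fit_replicate(
    model: EscapeResponseModel,
    V: np.ndarray,
    I: np.ndarray,
    rng: np.random.Generator,
    max_retries: int = 3,
) -> Tuple[Optional[EscapeResponseModel], int]:
    """Fit a bootstrap-replicate control model, retrying with new restarts."""
    failures = 0
    for _ in range(max_retries):
        m = clone(model)
        m.set_params(random_state=int(rng.integers(0, 2**31 - 1)))
        try:
            return m.fit(V, I), failures
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failures += 1
    return None, failures


def bootstrap_effect(
    profiles_control,
    control_currents,
    profiles_treated,
    treated_currents,
    model: EscapeResponseModel,
    B: int = 1000,
    seed: int = 0,
    n_bins: int = 5,
    refit: bool = True,
) -> EffectEstimate:
    """Delta I per bin with bootstrap SDs and Z scores.

    ``model`` is the control model (fitted, or unfitted and then fitted on
    the full control data). With ``refit=True`` every replicate refits the
    whole control pipeline on the resampled control cohort, as the error
    analysis requires; ``refit=False`` keeps the full-data model (a cheap
    smoke-test mode). Deterministic given (seed, B).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    Vc = np.atleast_2d(np.asarray(profiles_control, dtype=float))
    Vt = np.atleast_2d(np.asarray(profiles_treated, dtype=float))
    Ic = np.asarray(control_currents, dtype=float)
    It = np.asarray(treated_currents, dtype=float)
    model = _ensure_fitted(model, Vc, Ic)
    _, edges = quantile_bins(Ic, n_bins)
    point = delta_I(model.predict(Vc), Ic, model.predict(Vt), It, n_bins, edges)

    rng = np.random.default_rng(seed)
    deltas = np.full((B, n_bins), np.nan)
    overall = np.full(B, np.nan)
    n_failures = 0
    if not refit:
        dec_c_all = model.predict(Vc)
        dec_t_all = model.predict(Vt)
    for b in range(B):
        ic = rng.integers(0, Ic.size, Ic.size)
        it = rng.integers(0, It.size, It.size)
        if refit:
            mb, fails = _fit_replicate(model, Vc[ic], Ic[ic], rng)
            n_failures += fails
            if mb is None:
                continue
            dec_c = mb.predict(Vc[ic])
            dec_t = mb.predict(Vt[it])
        else:
            dec_c = dec_c_all[ic]
            dec_t = dec_t_all[it]
        j, _ = match_pairs(Ic[ic], It[it])
        diffs = dec_c - dec_t[j]
        deltas[b], _ = _binned_deltas(diffs, Ic[ic], edges, n_bins)
        overall[b] = diffs.mean()
    if n_failures > 0.05 * B:
        raise RuntimeError(
            f"{n_failures} replicate fit failures out of {B} bootstrap rounds"
        )
    sd = np.nanstd(deltas, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = point.delta_I_mA / sd
    point.delta_sd_mA = sd
    point.z_score = z
    point.overall_sd_mA = float(np.nanstd(overall, ddof=1))
    point.overall_z = float(point.overall_delta_I_mA / point.overall_sd_mA)
    point.B = B
    point.n_fit_failures = n_failures
    return point


def power_curve(
    profiles_control,
    control_currents,
    profiles_treated,
    treated_currents,
    model: EscapeResponseModel,
    bin_index: int,
    n_values: Sequence[int],
    B: int = 1000,
    seed: int = 0,
    n_bins: int = 5,
    refit: bool = True,
) -> PowerCurve:
    """Z score of the perceived-stimulus reduction vs. treated sample size.

    For each n, every replicate resamples the control cohort with
    replacement (refitting the control model when ``refit``), draws n
    treated trials with replacement from the target stimulus bin, pairs the
    resampled control trials of that bin with them and recomputes the bin's
    Delta I; the mean over replicates divided by their SD is Z(n).
    """
    Vc = np.atleast_2d(np.asarray(profiles_control, dtype=float))
    Vt = np.atleast_2d(np.asarray(profiles_treated, dtype=float))
    Ic = np.asarray(control_currents, dtype=float)
    It = np.asarray(treated_currents, dtype=float)
    model = _ensure_fitted(model, Vc, Ic)
    _, edges = quantile_bins(Ic, n_bins)
    treated_in_bin = np.flatnonzero(bin_by_edges(It, edges) == bin_index)
    control_in_bin_full = np.flatnonzero(bin_by_edges(Ic, edges) == bin_index)
    if treated_in_bin.size == 0 or control_in_bin_full.size == 0:
        raise ValueError(f"bin {bin_index} empty in one of the cohorts")

    rng = np.random.default_rng(seed)
    n_values = np.asarray(list(n_values), dtype=int)
    delta_of_n = np.empty(n_values.size)
    sd_of_n = np.empty(n_values.size)
    if not refit:
        dec_c_all = model.predict(Vc)
        dec_t_all = model.predict(Vt)
    for k, n in enumerate(n_values):
        reps = np.full(B, np.nan)
        for b in range(B):
            ic = rng.integers(0, Ic.size, Ic.size)
            sel = bin_by_edges(Ic[ic], edges) == bin_index
            it = treated_in_bin[rng.integers(0, treated_in_bin.size, int(n))]
            if not sel.any():
                continue
            if refit:
                mb, _ = _fit_replicate(model, Vc[ic], Ic[ic], rng)
                if mb is None:
                    continue
                dec_c = mb.predict(Vc[ic][sel])
                dec_t = mb.predict(Vt[it])
            else:
                dec_c = dec_c_all[ic][sel]
                dec_t = dec_t_all[it]
            j, _ = match_pairs(Ic[ic][sel], It[it])
            reps[b] = float(np.mean(dec_c - dec_t[j]))
        delta_of_n[k] = np.nanmean(reps)
        sd_of_n[k] = np.nanstd(reps, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_of_n = delta_of_n / sd_of_n
    return PowerCurve(
        n_values=n_values,
        delta_of_n=delta_of_n,
        sd_of_n=sd_of_n,
        z_of_n=z_of_n,
        B=B,
        bin_index=int(bin_index),
        bin_center_mA=float(Ic[control_in_bin_full].mean()),
    )
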