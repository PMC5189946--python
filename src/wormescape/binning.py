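"""Equal-count current bins used for presentation, variance and effects."""

from __future__ import annotations

from typing import Tuple

import numpy as np

__all__ = ["quantile_bins", "bin_by_edges"]


def quantile_bins(values, n_bins: int = 5) -> Tuple[np.ndarray, np.ndarray]:
    """Assign values to ``n_bins`` equal-count bins (rank-based).

    Bin of the value with rank r (0-based, stable sort) is
    ``r * n_bins // n``: 200 values give five bins of exactly 40; when n is
    not divisible the lower bins receive the extra values. Returns
    (assignments, inner edges); ``edges`` has length n_bins + 1 with
    -inf/+inf ends and midpoints between adjacent bins inside, so new values
    (e.g. treated-cohort currents) can be binned consistently with
    :func:`bin_by_edges`.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < n_bins:
        raise ValueError(f"cannot form {n_bins} bins from {n} values")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    ids = ranks * n_bins // n
    edges = np.empty(n_bins + 1)
    edges[0], edges[-1] = -np.inf, np.inf
    xs = x[order]
    counts = np.bincount(ids, minlength=n_bins)
    boundaries = np.cumsum(counts)[:-1]
    for k, b in enumerate(boundaries):
        edges[k + 1] = 0.5 * (xs[b - 1] + xs[b])
    return ids, edges


def bin_by_edges(values, edges) -> np.ndarray:
    """Bin assignments for new values given edges from :func:`quantile_bins`."""
    x = np.asarray(values, dtype=float)
    ids = np.searchsorted(np.asarray(edges)[1:-1], x, side="right")
    return ids
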