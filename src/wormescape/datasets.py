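"""Trial/cohort containers and the delimited-text dataset format.

A dataset is a pair of comma-separated files: a *manifest* with one row per
trial (``trial_id, worm_type, applied_current_mA``) and a wide *velocity
matrix* keyed by ``trial_id`` whose remaining columns are the signed
centre-of-mass velocity samples (pixels/s, 60 Hz, positive = forward).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Trial", "Cohort", "DatasetError", "read_dataset", "write_dataset"]

CURRENT_RANGE_MA = (0.0, 200.0)


class DatasetError(ValueError):
    """Structural problem in a trial manifest or velocity matrix."""


@dataclass
class Trial:
    """One stimulated worm: label, applied laser current and raw velocity."""

    trial_id: str
    worm_type: str
    applied_current_mA: float
    velocity_raw: np.ndarray
    stimulus_onset_s: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = CURRENT_RANGE_MA
        if not (lo <= self.applied_current_mA <= hi):
            raise DatasetError(
                f"trial {self.trial_id!r}: applied_current_mA="
                f"{self.applied_current_mA} outside [{lo}, {hi}]"
            )
        self.velocity_raw = np.asarray(self.velocity_raw, dtype=float)
        if self.velocity_raw.ndim != 1 or self.velocity_raw.size == 0:
            raise DatasetError(
                f"trial {self.trial_id!r}: velocity_raw must be a nonempty 1-D sequence"
            )


@dataclass
class Cohort:
    """All trials of one worm type (control, ibuprofen, mutant, ...)."""

    worm_type: str
    trials: List[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate trial_ids in cohort: {dupes}")
        for t in self.trials:
            if t.worm_type != self.worm_type:
                raise DatasetError(
                    f"trial {t.trial_id!r} has worm_type {t.worm_type!r}, "
                    f"cohort is {self.worm_type!r}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def currents_mA(self) -> np.ndarray:
        return np.array([t.applied_current_mA for t in self.trials], dtype=float)

    @property
    def velocity_matrix(self) -> np.ndarray:
        """Stacked raw traces, shape (n_trials, n_samples)."""
        return np.vstack([t.velocity_raw for t in self.trials])

    @property
    def trial_ids(self) -> List[str]:
        return [t.trial_id for t in self.trials]


def read_dataset(manifest_path, velocity_path) -> List[Cohort]:
    """Load a manifest + velocity-matrix pair into cohorts grouped by worm type.

    Cohorts appear in order of first appearance of their worm type; trial
    order within a cohort follows the manifest.
    """
    manifest = pd.read_csv(manifest_path, dtype={"trial_id": str, "worm_type": str})
    required = ["trial_id", "worm_type", "applied_current_mA"]
    missing = [c for c in required if c not in manifest.columns]
    if missing:
        raise DatasetError(f"manifest missing columns: {missing}")
    if manifest.empty:
        logger.warning("empty manifest %s: returning no cohorts", manifest_path)
        return []

    dupes = manifest["trial_id"][manifest["trial_id"].duplicated()].tolist()
    if dupes:
        raise DatasetError(f"duplicate trial_id(s) in manifest: {sorted(set(dupes))}")
    currents = pd.to_numeric(manifest["applied_current_mA"], errors="coerce")
    bad = np.flatnonzero(currents.isna().to_numpy())
    if bad.size:
        raise DatasetError(
            f"non-numeric applied_current_mA at manifest row(s) {bad.tolist()}"
        )
    lo, hi = CURRENT_RANGE_MA
    out = np.flatnonzero((currents < lo) | (currents > hi))
    if out.size:
        raise DatasetError(
            f"applied_current_mA outside [{lo}, {hi}] at manifest row(s) {out.tolist()}"
        )

    vel = pd.read_csv(velocity_path, dtype={"trial_id": str})
    if "trial_id" not in vel.columns:
        raise DatasetError("velocity file missing 'trial_id' column")
    vdupes = vel["trial_id"][vel["trial_id"].duplicated()].tolist()
    if vdupes:
        raise DatasetError(f"duplicate trial_id(s) in velocity file: {sorted(set(vdupes))}")
    vel = vel.set_index("trial_id")
    values = vel.to_numpy(dtype=float)
    lengths = np.sum(~np.isnan(values), axis=1)
    if lengths.size and not np.all(lengths == lengths[0]):
        uneven = [vel.index[i] for i in np.flatnonzero(lengths != lengths[0])]
        raise DatasetError(
            f"velocity row length mismatch (expected {int(lengths[0])} values) "
            f"for trial_id(s): {uneven}"
        )

    cohorts: dict[str, Cohort] = {}
    for row_i, row in enumerate(manifest.itertuples(index=False)):
        tid = row.trial_id
        if tid not in vel.index:
            raise DatasetError(f"trial_id {tid!r} has no velocity row")
        trial = Trial(
            trial_id=tid,
            worm_type=row.worm_type,
            applied_current_mA=float(currents.iloc[row_i]),
            velocity_raw=vel.loc[tid].to_numpy(dtype=float),
        )
        cohorts.setdefault(row.worm_type, Cohort(worm_type=row.worm_type))
        cohorts[row.worm_type].trials.append(trial)
    return list(cohorts.values())


def write_dataset(cohorts: Sequence[Cohort], manifest_path, velocity_path) -> None:
    """Write cohorts to the manifest + velocity CSV pair (12 significant digits)."""
    trials = [t for c in cohorts for t in c.trials]
    ids = [t.trial_id for t in trials]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DatasetError(f"refusing to write duplicate trial_ids: {dupes}")
    manifest = pd.DataFrame(
        {
            "trial_id": ids,
            "worm_type": [t.worm_type for t in trials],
            "applied_current_mA": [t.applied_current_mA for t in trials],
        }
    )
    manifest.to_csv(manifest_path, index=False, float_format="%.12g")
    if trials:
        mat = np.vstack([t.velocity_raw for t in trials])
        cols = [f"v{i}" for i in range(mat.shape[1])]
        vel = pd.DataFrame(mat, columns=cols)
        vel.insert(0, "trial_id", ids)
    else:
        vel = pd.DataFrame({"trial_id": []})
    vel.to_csv(velocity_path, index=False, float_format="%.12g")
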