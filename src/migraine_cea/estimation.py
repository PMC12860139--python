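"""Transition-matrix estimation from patient-level MMD panels.

Transitions are counted over all consecutive band pairs (baseline -> cycle 1
pooled with later cycles, one stationary matrix per arm).  Uncertainty comes
from a nonparametric bootstrap that resamples *patients* with replacement,
preserving within-patient correlation; the point estimate is the mean of the
resampled row-normalized proportion matrices and the SE their elementwise
standard deviation.  A from-band never observed in a resample falls back to
self-transition with probability 1, keeping the matrix stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import TransitionMatrix
from .states import N_BANDS, band_index_of_mmd


@dataclass
class BootstrapEstimate:
    """Bootstrap mean/SE of a per-cycle transition matrix for one arm."""

    arm: str
    mean: np.ndarray
    se: np.ndarray
    n_resamples: int

    def as_transition_matrix(self) -> TransitionMatrix:
        return TransitionMatrix(strategy=self.arm, p=self.mean, se=self.se)


def _band_paths(panel: pd.DataFrame) -> np.ndarray:
    """Per-patient band index sequences (baseline plus each cycle)."""
    cycle_cols = sorted(
        (c for c in panel.columns if c.startswith("mmd_c")),
        key=lambda c: int(c.removeprefix("mmd_c")),
    )
    if not cycle_cols:
        raise ValueError("panel has no mmd_c<k> columns")
    values = panel[["baseline_mmd", *cycle_cols]].to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("MMD values must be non-negative")
    return np.vectorize(band_index_of_mmd)(values)


def _count_from_paths(paths: np.ndarray) -> np.ndarray:
    counts = np.zeros((N_BANDS, N_BANDS), dtype=np.int64)
    for k in range(paths.shape[1] - 1):
        np.add.at(counts, (paths[:, k], paths[:, k + 1]), 1)
    return counts


def _proportions(counts: np.ndarray) -> np.ndarray:
    p = np.zeros((N_BANDS, N_BANDS))
    row_tot = counts.sum(axis=1)
    for i in range(N_BANDS):
        if row_tot[i] > 0:
            p[i] = counts[i] / row_tot[i]
        else:
            p[i, i] = 1.0  # unobserved from-band: self-transition
    return p


def _arm_paths(panel: pd.DataFrame, arm: str) -> np.ndarray:
    sub = panel[panel["arm"] == arm]
    if sub.empty:
        raise ValueError(f"no patients in arm {arm!r}")
    return _band_paths(sub)


def count_transitions(panel: pd.DataFrame, arm: str) -> np.ndarray:
    """6x6 from/to transition counts pooled over all cycles for one arm."""
    return _count_from_paths(_arm_paths(panel, arm))


def bootstrap_matrix(
    panel: pd.DataFrame,
    arm: str,
    n_resamples: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
) -> BootstrapEstimate:
    """Bootstrap mean and SE of the arm's transition matrix.

    With ``n_resamples=1`` the estimate equals the single-sample proportion
    matrix and all SEs are zero.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    paths = _arm_paths(panel, arm)
    n = paths.shape[0]
    rng = np.random.default_rng(seed)
    reps = np.empty((n_resamples, N_BANDS, N_BANDS))
    for r in range(n_resamples):
        idx = rng.integers(0, n, size=n) if n_resamples > 1 else np.arange(n)
        reps[r] = _proportions(_count_from_paths(paths[idx]))
    mean = reps.mean(axis=0)
    se = reps.std(axis=0, ddof=0)
    mean /= mean.sum(axis=1, keepdims=True)
    return BootstrapEstimate(arm=arm, mean=mean, se=se, n_resamples=n_resamples)
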