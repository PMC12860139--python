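"""Markov cohort engine: transition matrices and deterministic traces.

A strategy is described by a single row-stochastic 6x6 transition matrix
applied at the start of every cycle (stationary transitions, no mortality,
no discontinuation).  The cohort trace records the fraction of the cohort
in each MMD band after each cycle; all cost and QALY accrual reads from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import BAND_LABELS, N_BANDS

_ROW_TOL = 1e-9


@dataclass
class TransitionMatrix:
    """Row-stochastic per-cycle transition matrix for one strategy.

    ``p[i, j]`` is the probability of moving from band ``i`` to band ``j``
    within one cycle.  ``se`` optionally carries elementwise standard errors
    (e.g. from a bootstrap) used by the probabilistic sensitivity analysis.
    """

    strategy: str
    p: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_BANDS, N_BANDS):
            raise ValueError(f"expected a {N_BANDS}x{N_BANDS} matrix, got {self.p.shape}")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(self.p.sum(axis=1), 1.0, atol=_ROW_TOL, rtol=0):
            raise ValueError(
                "rows must sum to 1; renormalize first (see from_printed_table/normalize_rows)"
            )
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.p.shape:
                raise ValueError("se must have the same shape as p")
            if np.any(self.se < 0):
                raise ValueError("standard errors must be non-negative")


@dataclass
class InitialDistribution:
    """Baseline fraction of the cohort in each band."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (N_BANDS,):
            raise ValueError(f"expected {N_BANDS} weights, got shape {self.weights.shape}")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > _ROW_TOL:
            raise ValueError(f"weights must sum to 1, got {self.weights.sum()!r}")


@dataclass
class CohortTrace:
    """State occupancy over cycles; row 0 is the baseline distribution."""

    occupancy: np.ndarray  # (n_cycles + 1, N_BANDS)
    cycle_length_years: float
    n_cycles: int = field(init=False)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.ndim != 2 or self.occupancy.shape[1] != N_BANDS:
            raise ValueError("occupancy must be (n_cycles+1) x n_bands")
        if not np.allclose(self.occupancy.sum(axis=1), 1.0, atol=1e-8, rtol=0):
            raise ValueError("each occupancy row must sum to 1 (cohort conservation)")
        self.n_cycles = self.occupancy.shape[0] - 1


def normalize_rows(p: np.ndarray) -> np.ndarray:
    """Rescale each row of a non-negative matrix to sum exactly to 1."""
    p = np.asarray(p, dtype=float)
    sums = p.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("cannot normalize a row with zero total mass")
    return p / sums


def from_printed_table(column_major: np.ndarray, strategy: str,
                se_column_major: np.ndarray | None = None) -> TransitionMatrix:
    """Build a :class:`TransitionMatrix` from a table in printed orientation.

    The published transition table prints *from*-states as columns and
    *to*-states as rows, with columns summing to ~1 up to rounding.  This
    transposes to the row-stochastic convention and renormalizes each row so
    the probabilities sum exactly to 100%.

    Raises
    ------
    ValueError
        If any column sums outside [0.95, 1.05] (a mis-keyed table) or any
        entry is outside [0, 1].
    """
    cm = np.asarray(column_major, dtype=float)
    if cm.shape != (N_BANDS, N_BANDS):
        raise ValueError(f"expected a {N_BANDS}x{N_BANDS} table, got {cm.shape}")
    if np.any(cm < 0) or np.any(cm > 1):
        raise ValueError("table entries must lie in [0, 1]")
    col_sums = cm.sum(axis=0)
    bad = np.where((col_sums < 0.95) | (col_sums > 1.05))[0]
    if bad.size:
        details = ", ".join(
            f"{BAND_LABELS[j]!r} sums to {col_sums[j]:.3f}" for j in bad
        )
        raise ValueError(f"column sums outside [0.95, 1.05]: {details}")
    se = None
    if se_column_major is not None:
        se = np.asarray(se_column_major, dtype=float).T.copy()
    return TransitionMatrix(strategy=strategy, p=normalize_rows(cm.T), se=se)


def run_trace(init: InitialDistribution, tm: TransitionMatrix, n_cycles: int,
              cycle_length_years: float = 0.25) -> CohortTrace:
    """Advance the cohort ``n_cycles`` cycles: occupancy[k] = occupancy[k-1] @ p."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    occ = np.empty((n_cycles + 1, N_BANDS), dtype=float)
    occ[0] = init.weights
    for k in range(1, n_cycles + 1):
        # multiply-and-sum rather than BLAS matvec: bit-reproducible across
        # array alignments, which the degenerate-PSA equivalence relies on
        occ[k] = (occ[k - 1][:, None] * tm.p).sum(axis=0)
    return CohortTrace(occupancy=occ, cycle_length_years=cycle_length_years)


def expected_mmd(trace: CohortTrace,
                 band_values: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Occupancy-weighted mean MMD per cycle and the change from baseline.

    Returns
    -------
    per_cycle : ndarray
        Expected MMD at baseline and after each cycle (length n_cycles+1).
    change : float
        Baseline expected MMD minus final-cycle expected MMD (positive means
        migraine days were reduced).
    """
    from .states import BANDS, DEFAULT_BAND_VALUES

    if band_values is None:
        band_values = np.asarray(DEFAULT_BAND_VALUES, dtype=float)
    else:
        band_values = np.asarray(band_values, dtype=float)
        if band_values.shape != (N_BANDS,):
            raise ValueError(f"band_values must have length {N_BANDS}")
        import warnings

        for v, band in zip(band_values, BANDS):
            lo, hi = band.lower, band.upper
            if v < lo or (hi is not None and v > hi):
                warnings.warn(
                    f"band value {v} lies outside band {band.label!r}",
                    stacklevel=2,
                )
    per_cycle = (trace.occupancy * band_values).sum(axis=1)
    return per_cycle, float(per_cycle[0] - per_cycle[-1])
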