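"""Synthetic trial cohorts: patient-level panels emulating the pivotal trials.

The economic model was parameterized from three randomized trials of
quarterly intravenous anti-CGRP prophylaxis (two in episodic/chronic
migraine, one in patients with prior preventive failures).  Patient-level
data are not public, so this module generates trial-like cohorts instead:
baseline monthly migraine days are drawn from scaled Beta distributions
matched to each trial's reported baseline mean (support 4-28 days, reflecting
the >=4 MMD inclusion criterion), sex and age are sampled independently of
MMD, and per-cycle MMD trajectories follow a supplied per-arm transition
matrix, with the concrete day count drawn uniformly within the new band.

The same machinery derives the model's baseline state distribution, either
analytically (exact mixture band probabilities) or empirically from a
generated cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .markov import InitialDistribution, TransitionMatrix
from .states import BANDS, N_BANDS, band_index_of_mmd

ARMS = ("eptinezumab", "placebo")


@dataclass(frozen=True)
class TrialProfile:
    """Summary characteristics of one source trial.

    ``concentration`` is the Beta pseudo-sample-size controlling baseline MMD
    spread (only the mean is published); ``weight`` is the trial's share of
    the pooled cohort.
    """

    name: str
    baseline_mmd_mean: float
    mmd_low: float = 4.0
    mmd_high: float = 28.0
    concentration: float = 10.0
    female_prop: float = 0.78
    age_mean: float = 42.3
    age_sd: float = 11.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.mmd_low < self.baseline_mmd_mean < self.mmd_high:
            raise ValueError(
                f"trial {self.name!r}: baseline mean {self.baseline_mmd_mean} "
                f"outside the open support ({self.mmd_low}, {self.mmd_high})"
            )
        if self.concentration <= 0 or self.weight < 0:
            raise ValueError("concentration must be > 0 and weight >= 0")

    def beta_params(self) -> tuple[float, float]:
        """Shape parameters of the scaled Beta for baseline MMD."""
        mu = (self.baseline_mmd_mean - self.mmd_low) / (self.mmd_high - self.mmd_low)
        return mu * self.concentration, (1.0 - mu) * self.concentration


def default_trial_profiles() -> tuple[TrialProfile, ...]:
    """The three source-trial profiles with published baseline MMD means
    (10.0 episodic, 20.4 chronic, 14.5 mixed) and equal pooling weights."""
    return (
        TrialProfile("PROMISE-1", baseline_mmd_mean=10.0, age_mean=40.0, weight=1 / 3),
        TrialProfile("PROMISE-2", baseline_mmd_mean=20.4, age_mean=41.0, weight=1 / 3),
        TrialProfile("DELIVER", baseline_mmd_mean=14.5, age_mean=44.6, weight=1 / 3),
    )


def _band_cut_points() -> np.ndarray:
    # Half-up rounding makes band b cover real MMD in [lower-0.5, upper+0.5).
    cuts = []
    for band in BANDS[:-1]:
        cuts.append(band.upper + 0.5)
    return np.asarray(cuts)


def band_probabilities(profiles: tuple[TrialProfile, ...] | list[TrialProfile]) -> np.ndarray:
    """Exact band membership probabilities of the trial-weighted Beta mixture."""
    weights = np.array([p.weight for p in profiles], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("trial weights must sum to a positive value")
    weights = weights / weights.sum()
    cuts = _band_cut_points()
    probs = np.zeros(N_BANDS)
    for w, prof in zip(weights, profiles):
        a, b = prof.beta_params()
        scaled = np.clip((cuts - prof.mmd_low) / (prof.mmd_high - prof.mmd_low), 0.0, 1.0)
        cdf = stats.beta.cdf(scaled, a, b)
        edges = np.concatenate([[0.0], cdf, [1.0]])
        probs += w * np.diff(edges)
    return probs / probs.sum()


def initial_distribution_from_profiles(
    profiles: tuple[TrialProfile, ...] | list[TrialProfile],
) -> InitialDistribution:
    """Baseline state distribution as the exact mixture band probabilities."""
    return InitialDistribution(weights=band_probabilities(profiles))


def generate_cohort(
    profiles: tuple[TrialProfile, ...] | list[TrialProfile],
    n_patients: int,
    arm_matrices: dict[str, TransitionMatrix],
    n_cycles: int = 2,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Simulate a patient-level longitudinal panel.

    Each patient is assigned a source trial by weight, a baseline MMD from
    that trial's scaled Beta, sex/age independently, and an arm by 1:1
    allocation; each cycle the band evolves by the arm's transition row and
    a concrete MMD is drawn uniformly within the new band (24-30 days for
    the open-ended top band).

    Returns a DataFrame with columns ``patient_id, arm, trial, baseline_mmd,
    mmd_c1..mmd_cK, age, female``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    missing = [a for a in arm_matrices if a not in ARMS]
    if missing:
        raise ValueError(f"unknown arms {missing}; expected subset of {ARMS}")
    rng = np.random.default_rng(seed)
    profiles = tuple(profiles)
    weights = np.array([p.weight for p in profiles], dtype=float)
    weights = weights / weights.sum()

    trial_idx = rng.choice(len(profiles), size=n_patients, p=weights)
    baseline = np.empty(n_patients)
    age = np.empty(n_patients)
    for i, prof in enumerate(profiles):
        mask = trial_idx == i
        n_i = int(mask.sum())
        if n_i == 0:
            continue
        a, b = prof.beta_params()
        baseline[mask] = prof.mmd_low + (prof.mmd_high - prof.mmd_low) * rng.beta(a, b, n_i)
        age[mask] = np.clip(rng.normal(prof.age_mean, prof.age_sd, n_i), 18.0, 75.0)
    female = rng.random(n_patients) < np.array([profiles[t].female_prop for t in trial_idx])

    arms = np.array(ARMS)[np.arange(n_patients) % 2]  # exact 1:1 allocation
    rng.shuffle(arms)

    mmd = np.empty((n_patients, n_cycles))
    band_bounds = [(b.lower, b.upper if b.upper is not None else 30) for b in BANDS]
    for i in range(n_patients):
        state = band_index_of_mmd(baseline[i])
        row_cum = {}
        tm = arm_matrices[arms[i]]
        for k in range(n_cycles):
            u = rng.random()
            if state not in row_cum:
                row_cum[state] = np.cumsum(tm.p[state])
            state = int(np.searchsorted(row_cum[state], u, side="right"))
            state = min(state, N_BANDS - 1)
            lo, hi = band_bounds[state]
            mmd[i, k] = lo + (hi - lo) * rng.random()

    data = {
        "patient_id": [f"pt{i:06d}" for i in range(n_patients)],
        "arm": arms,
        "trial": [profiles[t].name for t in trial_idx],
        "baseline_mmd": baseline,
    }
    for k in range(n_cycles):
        data[f"mmd_c{k + 1}"] = mmd[:, k]
    data["age"] = age
    data["female"] = female.astype(int)
    return pd.DataFrame(data)


def initial_distribution_from_cohort(panel: pd.DataFrame) -> InitialDistribution:
    """Empirical baseline band distribution of a generated (or real) panel."""
    counts = np.zeros(N_BANDS)
    for v in panel["baseline_mmd"].to_numpy():
        counts[band_index_of_mmd(float(v))] += 1
    return InitialDistribution(weights=counts / counts.sum())
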