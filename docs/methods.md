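# Methods

## The decision problem

`migraine_cea` implements a cost-utility analysis of quarterly intravenous
anti-CGRP migraine prophylaxis (eptinezumab 100 mg) against placebo from a
health-payer perspective in Taiwan. The model is a Markov cohort model with
six health states defined by monthly migraine days (MMD): episodic-migraine
bands 0–3, 4–9 and 10–14 days, and chronic-migraine bands 15–19, 20–24 and
24+ days (chronic migraine begins at 15 MMD). The horizon is six months in
two quarterly cycles, matching the drug's dosing interval; mortality and
treatment discontinuation are excluded (negligible at this age and horizon,
and <1% discontinuation in the source trials).

Each arm is described by a stationary per-cycle transition matrix, a per-band
utility set, and a cost schedule. The cohort transitions at the start of each
cycle; utilities and costs accrue on the post-transition occupancy. Outcomes
are discounted costs (2024 USD), discounted QALYs (utility × 0.25 yr per
cycle), and the ICER on unrounded increments. Cost-effectiveness is judged
against willingness-to-pay thresholds of $32,327 (1× GDP per capita) and
$96,981 (3×).

## Transition matrices

The published tables print *from*-states as columns and *to*-states as rows,
with columns summing to ~1 up to rounding (0.99–1.01). Ingest transposes to
row-stochastic form and renormalizes each row to sum exactly to 100%;
renormalization never moves an entry by more than the 0.01 rounding slack,
which is asserted in tests.

When patient-level panels are available (real or synthetic), transition
matrices are estimated by pooling all consecutive band pairs — baseline to
cycle 1 together with later cycles, one stationary matrix per arm — and
bootstrapped by resampling *patients* with replacement (default 1,000
resamples). The point estimate is the mean of the resampled row-normalized
proportion matrices, the SE their elementwise standard deviation; a from-band
absent from a resample falls back to self-transition 1, keeping rows
stochastic. Resampling patients rather than transitions preserves
within-patient correlation.

## Baseline distribution

The baseline state distribution is not published. The default derives it
from the published trial baseline MMD means (10.0, 20.4, 14.5 days) via a
trial-weighted mixture of Beta distributions scaled to support [4, 28] days
(the ≥4 MMD inclusion criterion), equal trial weights (trial sizes are not
published here), Beta concentration 10 (only the means are published). The
shipped default uses the *exact* band probabilities of that mixture — the
large-sample limit of sampling patient baselines — so the base case is fully
deterministic; an empirical derivation from a generated cohort is available
and converges to it. Both are user-overridable in the configuration.

## Costs

- Drug: $1,708 per dose, one dose per cycle, intervention arm only; sampled
  Uniform ±20% in the PSA (the only cost-variation magnitude stated for it).
- Administration: per infusion, both arms (the placebo arm incurs
  administrative costs only). The magnitude is not published; default $150.
- Medication: per cycle, resolved by the current band's chronicity — chronic
  bands accrue chronic-migraine acute + prevention costs ($270.0 + $37.0),
  episodic bands the episodic costs ($184.0 + $27.4). Treating these as
  per-cycle (rather than per-horizon) accruals is a documented assumption;
  it is what makes state occupancy matter economically and places the
  placebo six-month total near its published value. The non-state-specific
  acute-medication row ($394.9) is retained in the inputs as an alternative
  scenario but unused in the base case to avoid double counting.
- Diagnostics/procedures (MRI $195.9, CT $114.5, ECG $4.5, skull X-ray $6.0,
  blood test $6.0, botulinum toxin $110.4, TENS $9.6, occipital nerve block
  $0.7): one-time expected cost at model entry, unit cost × use probability.
  The use probabilities are cited to an external source and not published;
  they are shipped as overridable calibration defaults chosen once so the
  placebo-arm six-month total lands near its published value (~$1,065) —
  calibrated against that total only, never against the ICER.

Discounting is 3%/yr on both costs and QALYs: the first cycle undiscounted,
later cycles at (1+r)^(−(k−1)·cycle-length). With a six-month horizon the
discount-timing convention moves results by well under 1%. No half-cycle
correction is applied (transition-at-cycle-start convention).

## Sensitivity analyses

**One-way (tornado).** Each parameter is re-solved alone at its bounds:
utilities and transition probabilities ±10% (perturbed rows renormalized,
utilities clipped to (0,1)), costs ±20%. Dominance at a bound is reported as
an explicit sentinel, never a number. Entries are sorted by bar width.

**Probabilistic.** 10,000 joint independent draws: utilities Beta
(method-of-moments from mean/SD, arm-specific), costs Gamma (shared between
arms and drawn once per iteration, so arm-neutral items cancel in ΔC), drug
cost Uniform, each transition from-row Dirichlet restricted to its nonzero
support. Dirichlet concentrations come from bootstrap SEs when present (ν
solving the largest-variance entry's SE by moment matching); without SEs the
default is ν = 100 per row (SE ≈ 0.05 on a 0.5 entry). Every published
medication-cost SD equals mean/2, so that ratio is the default SD for
diagnostic items whose SD is unpublished. Parameters with zero SD (or
degenerate Uniform bounds) are held fixed, making an all-degenerate PSA
reproduce the base case bit-for-bit — this required replacing BLAS
matrix-vector products with multiply-and-sum reductions in the trace and
accrual kernels, whose results do not depend on array alignment.

Correlations between parameters are not modeled (a documented limitation).
The CEAC evaluates P(λ·ΔE − ΔC > 0) on a grid of 0–150,000 USD/QALY in
1,000 steps, covering both thresholds; ties go to the comparator. One root
seed spawns per-draw substreams, so results are reproducible independent of
evaluation order.

## Synthetic cohorts

The generator emulates the three source trials: baseline MMD from the scaled
Beta mixture above, ~78% female, ages normal around 40.0–44.6 (SD 11 years,
clipped to the 18–75 enrollment window; SDs are not published), sampled
independently of MMD; 1:1 arm allocation; per cycle the band evolves by the
arm's transition row and a concrete MMD is drawn uniformly within the new
band (24–30 days for the top band). It reproduces the marginal features the
trials report — not real patients' within-person MMD autocorrelation,
dropout, or placebo-response dynamics — so passing round-trip tests shows
the estimation machinery is correct, not that the trial data would yield
these exact matrices. Age and sex are generated for panel realism and are
unused by the economic model.

## Known tensions in the published inputs

The published six-month MMD reductions (5.8 intervention / 3.8 placebo) are
not reachable from the published per-cycle matrices applied twice, which
give 8.9 / 6.0 days from any baseline distribution consistent with the trial
means; a *single* application gives 5.2 / 3.3 (between-arm difference 1.9 vs
the published 2.0). The published QALYs and ICER, by contrast, are matched
well by the two-cycle trace (0.3585 / 0.3123, ICER ≈ 73,280). This package
follows the stated model structure — transitions at the start of every
cycle — and reports the trace-based MMD change as computed, leaving the
discrepancy visible rather than switching conventions per outcome.

## Problem sizes and numerical defaults

Base case: 2 cycles, solved in milliseconds. PSA: 10,000 draws (~6 s).
Bootstrap: 1,000 resamples at 1,000-patient cohorts in tests. Row-sum and
conservation tolerances 1e-9; Beta/Gamma moment conversions validate SD
against the mean (a Beta SD must satisfy s² < m(1−m)) and raise naming the
offending parameter rather than silently clipping.
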