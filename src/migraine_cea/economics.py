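"""Cost and QALY accrual, discounting, ICER and net monetary benefit.

Accrual convention: the cohort transitions at the start of each cycle and
utilities/costs accrue on the post-transition occupancy (trace rows
1..n_cycles).  The first cycle is undiscounted; later cycles are discounted
exponentially at the annual rate.  One-time entry costs (diagnostic work-up,
expected over per-item use probabilities) are charged undiscounted at model
entry.  All monetary values are 2024 US dollars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .markov import CohortTrace
from .states import BANDS, N_BANDS


@dataclass
class UtilitySet:
    """Per-band utility means and SDs for one strategy (Beta-distributed)."""

    strategy: str
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (N_BANDS,) or self.sd.shape != (N_BANDS,):
            raise ValueError(f"utility mean/sd must have length {N_BANDS}")
        if np.any(self.mean <= 0) or np.any(self.mean >= 1):
            raise ValueError("utility means must lie strictly in (0, 1)")
        if np.any(self.sd < 0):
            raise ValueError("utility SDs must be non-negative")

    def beta_params(self) -> tuple[np.ndarray, np.ndarray]:
        """Method-of-moments Beta(alpha, beta) parameters per band."""
        m, s = self.mean, self.sd
        var = s**2
        if np.any(var >= m * (1 - m)):
            bad = [BANDS[i].label for i in np.where(var >= m * (1 - m))[0]]
            raise ValueError(f"SD too large for a Beta with the given mean: bands {bad}")
        nu = m * (1 - m) / var - 1
        return m * nu, (1 - m) * nu


@dataclass(frozen=True)
class CostItem:
    """One cost input: mean (USD), SD for its sampling distribution, and an
    optional per-patient use probability (for one-time entry items)."""

    name: str
    mean: float
    sd: float = 0.0
    use_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError(f"cost item {self.name!r}: mean and SD must be >= 0")
        if not 0.0 <= self.use_prob <= 1.0:
            raise ValueError(f"cost item {self.name!r}: use_prob must be in [0, 1]")

    def gamma_params(self) -> tuple[float, float]:
        """Method-of-moments Gamma(shape, scale); requires SD > 0."""
        if self.sd <= 0:
            raise ValueError(f"cost item {self.name!r} has SD 0; no Gamma defined")
        shape = (self.mean / self.sd) ** 2
        scale = self.sd**2 / self.mean
        return shape, scale


@dataclass
class CostSchedule:
    """All cost inputs for one strategy.

    ``drug_cost_per_dose`` applies only when the strategy's drug is active;
    ``admin_cost_per_infusion`` applies to every arm (placebo infusions incur
    administration costs too).  Medication costs are per cycle and depend on
    chronicity: CM bands (>=15 MMD) accrue the CM acute+prevention costs,
    EM bands the EM costs.  ``entry_items`` are one-time diagnostic/procedure
    items charged at model entry as unit cost x use probability.
    """

    drug_cost_per_dose: float = 0.0
    doses_per_cycle: int = 1
    drug_cost_low: float | None = None  # Uniform bounds for the PSA
    drug_cost_high: float | None = None
    admin_cost_per_infusion: float = 0.0
    cm_acute: CostItem = field(default_factory=lambda: CostItem("cm_acute", 0.0))
    cm_prevention: CostItem = field(default_factory=lambda: CostItem("cm_prevention", 0.0))
    em_acute: CostItem = field(default_factory=lambda: CostItem("em_acute", 0.0))
    em_prevention: CostItem = field(default_factory=lambda: CostItem("em_prevention", 0.0))
    entry_items: tuple[CostItem, ...] = ()

    def __post_init__(self) -> None:
        if self.drug_cost_per_dose < 0 or self.admin_cost_per_infusion < 0:
            raise ValueError("costs must be non-negative")
        if self.doses_per_cycle < 0:
            raise ValueError("doses_per_cycle must be >= 0")
        if self.drug_cost_low is None:
            self.drug_cost_low = self.drug_cost_per_dose
        if self.drug_cost_high is None:
            self.drug_cost_high = self.drug_cost_per_dose
        if not self.drug_cost_low <= self.drug_cost_high:
            raise ValueError("drug cost Uniform bounds must satisfy low <= high")

    def per_band_cycle_cost(self) -> np.ndarray:
        """Cycle medication cost for a patient in each band (CM vs EM)."""
        cm = self.cm_acute.mean + self.cm_prevention.mean
        em = self.em_acute.mean + self.em_prevention.mean
        return np.array([cm if b.is_chronic else em for b in BANDS])

    def expected_entry_cost(self) -> float:
        """One-time expected diagnostic/procedure cost at model entry."""
        return float(sum(it.mean * it.use_prob for it in self.entry_items))

    def scaled(self, **multipliers: float) -> "CostSchedule":
        """Return a copy with named components multiplied (for OWSA)."""
        out = replace(self)
        for key, f in multipliers.items():
            if key == "drug_cost":
                out.drug_cost_per_dose = self.drug_cost_per_dose * f
                out.drug_cost_low = self.drug_cost_low * f
                out.drug_cost_high = self.drug_cost_high * f
            elif key == "admin_cost":
                out.admin_cost_per_infusion = self.admin_cost_per_infusion * f
            elif key == "entry":
                out.entry_items = tuple(
                    replace(it, mean=it.mean * f) for it in self.entry_items
                )
            elif key in ("cm_acute", "cm_prevention", "em_acute", "em_prevention"):
                item: CostItem = getattr(self, key)
                setattr(out, key, replace(item, mean=item.mean * f))
            else:
                raise KeyError(f"unknown cost component {key!r}")
        return out


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate and cycle length (fraction of a year)."""

    annual_rate: float = 0.03
    cycle_length_years: float = 0.25

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if self.cycle_length_years <= 0:
            raise ValueError("cycle length must be positive")


def discount_factor(cycle_index: int, spec: DiscountSpec) -> float:
    """Discount factor for a cycle (1-based); the first cycle is undiscounted."""
    if cycle_index < 1:
        raise ValueError("cycle_index must be >= 1")
    return (1.0 + spec.annual_rate) ** (-(cycle_index - 1) * spec.cycle_length_years)


def accrue_qalys(trace: CohortTrace, utilities: UtilitySet, spec: DiscountSpec) -> float:
    """Total discounted QALYs over the trace.

    Each cycle contributes discount x cycle-length x (occupancy . utility)
    on the post-transition occupancy.
    """
    total = 0.0
    for k in range(1, trace.n_cycles + 1):
        u = float((trace.occupancy[k] * utilities.mean).sum())
        total += discount_factor(k, spec) * spec.cycle_length_years * u
    return total


def accrue_costs(trace: CohortTrace, costs: CostSchedule, spec: DiscountSpec,
                 drug_active: bool) -> tuple[float, dict[str, float]]:
    """Total discounted cost (USD) over the trace, with a per-item breakdown.

    Returns ``(total, breakdown)`` where breakdown has keys ``drug``,
    ``administration``, ``medication`` and ``entry``.
    """
    band_cost = costs.per_band_cycle_cost()
    drug = admin = medication = 0.0
    for k in range(1, trace.n_cycles + 1):
        df = discount_factor(k, spec)
        if drug_active:
            drug += df * costs.drug_cost_per_dose * costs.doses_per_cycle
        admin += df * costs.admin_cost_per_infusion * max(costs.doses_per_cycle, 1)
        medication += df * float((trace.occupancy[k] * band_cost).sum())
    entry = costs.expected_entry_cost()
    breakdown = {
        "drug": drug,
        "administration": admin,
        "medication": medication,
        "entry": entry,
    }
    return drug + admin + medication + entry, breakdown


@dataclass
class CeResult:
    """Pairwise cost-effectiveness comparison (intervention vs comparator)."""

    strategy: str
    comparator: str
    cost: float
    comparator_cost: float
    qalys: float
    comparator_qalys: float
    incremental_cost: float = field(init=False)
    incremental_qalys: float = field(init=False)
    icer: float | None = field(init=False)
    dominance: str | None = field(init=False)

    def __post_init__(self) -> None:
        dc = self.cost - self.comparator_cost
        de = self.qalys - self.comparator_qalys
        self.incremental_cost = dc
        self.incremental_qalys = de
        if dc <= 0 and de >= 0 and (dc < 0 or de > 0):
            self.dominance = "dominant"
        elif dc >= 0 and de <= 0 and (dc > 0 or de < 0):
            self.dominance = "dominated"
        else:
            self.dominance = None
        self.icer = dc / de if de != 0 else None


def compute_icer(strategy: str, comparator: str, cost: float, comparator_cost: float,
                 qalys: float, comparator_qalys: float) -> CeResult:
    """ICER on unrounded increments, with dominance flags.

    A zero QALY difference yields ``icer=None`` rather than an exception.
    """
    return CeResult(strategy, comparator, cost, comparator_cost, qalys, comparator_qalys)


def net_monetary_benefit(cost: float, qalys: float, wtp: float) -> float:
    """NMB = wtp x QALYs - cost; higher is better at threshold ``wtp``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * qalys - cost


def icer_repr(result: CeResult) -> str:
    """Human/CSV representation of an ICER, using explicit dominance sentinels."""
    if result.dominance == "dominant":
        return "dominant"
    if result.dominance == "dominated":
        return "dominated"
    if result.icer is None or not math.isfinite(result.icer):
        return "undefined"
    return f"{result.icer:.2f}"
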