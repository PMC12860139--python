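"""The assembled decision model: two strategies evaluated deterministically.

``DecisionModel`` bundles everything a single deterministic solve needs —
per-strategy transition matrix, utility set and cost schedule, the shared
baseline distribution, horizon and discounting — and ``evaluate`` produces
traces, discounted costs/QALYs, expected-MMD summaries and the incremental
comparison.  Sensitivity analyses re-solve perturbed copies of the model.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .economics import (
    CeResult,
    CostSchedule,
    DiscountSpec,
    UtilitySet,
    accrue_costs,
    accrue_qalys,
    compute_icer,
)
from .markov import CohortTrace, InitialDistribution, TransitionMatrix, expected_mmd, run_trace
from .states import DEFAULT_BAND_VALUES


@dataclass
class StrategyInputs:
    """Everything specific to one arm of the comparison."""

    name: str
    transitions: TransitionMatrix
    utilities: UtilitySet
    costs: CostSchedule
    drug_active: bool


@dataclass
class StrategyOutcome:
    """Deterministic results for one arm."""

    name: str
    trace: CohortTrace
    qalys: float
    cost: float
    cost_breakdown: dict[str, float]
    mmd_per_cycle: np.ndarray
    mmd_change: float


@dataclass
class ModelResult:
    """Full deterministic solve: per-arm outcomes plus the incremental pair."""

    outcomes: dict[str, StrategyOutcome]
    ce: CeResult


@dataclass
class DecisionModel:
    """A two-strategy Markov cohort cost-utility model.

    The first strategy in ``strategies`` is the intervention, the second the
    comparator; the incremental comparison is intervention vs comparator.
    """

    strategies: list[StrategyInputs]
    init: InitialDistribution
    n_cycles: int = 2
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    wtp_thresholds: tuple[float, ...] = (32_327.0, 96_981.0)
    band_values: tuple[float, ...] = DEFAULT_BAND_VALUES

    def __post_init__(self) -> None:
        if len(self.strategies) != 2:
            raise ValueError("exactly two strategies (intervention, comparator) required")

    @property
    def intervention(self) -> StrategyInputs:
        return self.strategies[0]

    @property
    def comparator(self) -> StrategyInputs:
        return self.strategies[1]

    def strategy(self, name: str) -> StrategyInputs:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    def copy(self) -> "DecisionModel":
        return copy.deepcopy(self)

    def evaluate(self) -> ModelResult:
        """Solve the model deterministically at its current inputs."""
        outcomes: dict[str, StrategyOutcome] = {}
        for s in self.strategies:
            trace = run_trace(self.init, s.transitions, self.n_cycles,
                              self.discount.cycle_length_years)
            qalys = accrue_qalys(trace, s.utilities, self.discount)
            cost, breakdown = accrue_costs(trace, s.costs, self.discount, s.drug_active)
            per_cycle, change = expected_mmd(trace, np.asarray(self.band_values))
            outcomes[s.name] = StrategyOutcome(
                name=s.name, trace=trace, qalys=qalys, cost=cost,
                cost_breakdown=breakdown, mmd_per_cycle=per_cycle, mmd_change=change,
            )
        a, b = outcomes[self.intervention.name], outcomes[self.comparator.name]
        ce = compute_icer(a.name, b.name, a.cost, b.cost, a.qalys, b.qalys)
        return ModelResult(outcomes=outcomes, ce=ce)
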