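"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis re-solves the model with a single parameter at its low or
high bound (treatment outcomes and utilities +/-10%, costs +/-20%), holding
everything else at base values; perturbed transition rows are renormalized
and perturbed utilities clipped to (0, 1).

The probabilistic analysis draws all parameters jointly and independently —
utilities from method-of-moments Beta, costs from method-of-moments Gamma,
the drug acquisition cost from a Uniform over its configured bounds, and
each transition from-row from a Dirichlet over its nonzero support with
concentrations matched to the bootstrap standard errors — then solves the
model deterministically at the draw.  Parameters with zero SD (or degenerate
bounds) are held fixed, so an all-degenerate draw reproduces the base case
exactly.  Cost items shared by both arms are drawn once per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .economics import net_monetary_benefit
from .model import DecisionModel
from .states import BAND_LABELS, N_BANDS

SHARED_COST_ITEMS = ("cm_acute", "cm_prevention", "em_acute", "em_prevention")


# ---------------------------------------------------------------------------
# One-way (tornado) analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OwsaSpec:
    """One parameter to vary, with low/high multipliers around base.

    ``parameter`` identifiers:
      - ``utility:<arm>:<band>``
      - ``transition:<arm>:<from>-><to>``
      - ``cost:drug`` (drug acquisition), ``cost:admin``, ``cost:entry``
        (the diagnostic bundle), ``cost:<cm|em>_<acute|prevention>``
    """

    parameter: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < 1.0 < self.high:
            raise ValueError(f"{self.parameter}: require low < 1 < high")


@dataclass
class TornadoEntry:
    """ICER at a parameter's two bounds; ``None`` marks dominance at a bound."""

    parameter: str
    icer_low: float | None
    icer_high: float | None
    low_label: str
    high_label: str
    width: float = field(init=False)

    def __post_init__(self) -> None:
        if self.icer_low is None or self.icer_high is None:
            self.width = float("inf")  # bar runs to the plot boundary
        else:
            self.width = abs(self.icer_high - self.icer_low)


def default_owsa_specs(model: DecisionModel) -> list[OwsaSpec]:
    """The full published perturbation set: utilities and every nonzero
    transition probability +/-10%, cost parameters +/-20%."""
    specs: list[OwsaSpec] = []
    for s in model.strategies:
        for band in BAND_LABELS:
            specs.append(OwsaSpec(f"utility:{s.name}:{band}", 0.9, 1.1))
    for s in model.strategies:
        for i in range(N_BANDS):
            for j in range(N_BANDS):
                if s.transitions.p[i, j] > 0:
                    specs.append(
                        OwsaSpec(
                            f"transition:{s.name}:{BAND_LABELS[i]}->{BAND_LABELS[j]}",
                            0.9, 1.1,
                        )
                    )
    specs.append(OwsaSpec("cost:drug", 0.8, 1.2))
    for item in SHARED_COST_ITEMS:
        specs.append(OwsaSpec(f"cost:{item}", 0.8, 1.2))
    specs.append(OwsaSpec("cost:entry", 0.8, 1.2))
    if any(s.costs.admin_cost_per_infusion > 0 for s in model.strategies):
        specs.append(OwsaSpec("cost:admin", 0.8, 1.2))
    return specs


def perturb(model: DecisionModel, parameter: str, multiplier: float) -> DecisionModel:
    """A copy of the model with one parameter scaled by ``multiplier``."""
    m = model.copy()
    kind, _, rest = parameter.partition(":")
    if kind == "utility":
        arm, _, band = rest.partition(":")
        s = m.strategy(arm)
        i = BAND_LABELS.index(band)
        value = s.utilities.mean[i] * multiplier
        eps = 1e-9
        s.utilities.mean[i] = float(np.clip(value, eps, 1.0 - eps))
    elif kind == "transition":
        arm, _, move = rest.partition(":")
        frm, _, to = move.partition("->")
        s = m.strategy(arm)
        i, j = BAND_LABELS.index(frm), BAND_LABELS.index(to)
        p = s.transitions.p
        p[i, j] *= multiplier
        row_sum = p[i].sum()
        if row_sum <= 0:
            raise ValueError(f"perturbing {parameter} left row {frm!r} with no mass")
        p[i] /= row_sum
    elif kind == "cost":
        if rest == "drug":
            for s in m.strategies:
                if s.drug_active:
                    s.costs = s.costs.scaled(drug_cost=multiplier)
        elif rest == "admin":
            for s in m.strategies:
                s.costs = s.costs.scaled(admin_cost=multiplier)
        elif rest == "entry":
            for s in m.strategies:
                s.costs = s.costs.scaled(entry=multiplier)
        elif rest in SHARED_COST_ITEMS:
            for s in m.strategies:
                s.costs = s.costs.scaled(**{rest: multiplier})
        else:
            raise KeyError(f"unknown cost parameter {rest!r}")
    else:
        raise KeyError(f"unknown parameter kind {kind!r} in {parameter!r}")
    return m


def run_owsa(model: DecisionModel, specs: list[OwsaSpec] | None = None) -> list[TornadoEntry]:
    """Re-solve the model at each parameter's bounds; entries sorted by
    tornado bar width, widest first."""
    if specs is None:
        specs = default_owsa_specs(model)
    entries: list[TornadoEntry] = []
    for spec in specs:
        bound_icers: list[float | None] = []
        labels: list[str] = []
        for mult in (spec.low, spec.high):
            ce = perturb(model, spec.parameter, mult).evaluate().ce
            if ce.dominance is not None:
                bound_icers.append(None)
                labels.append(ce.dominance)
            else:
                bound_icers.append(ce.icer)
                labels.append(f"{ce.icer:.2f}" if ce.icer is not None else "undefined")
        entries.append(
            TornadoEntry(spec.parameter, bound_icers[0], bound_icers[1],
                         labels[0], labels[1])
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PsaDraw:
    """One joint parameter draw and its deterministic model solve."""

    cost: dict[str, float]
    qalys: dict[str, float]
    delta_cost: float
    delta_qalys: float


@dataclass
class PsaResult:
    """All PSA draws plus summary statistics.

    ``prob_cost_effective`` maps each configured WTP threshold to the
    fraction of draws in which the intervention has the higher net monetary
    benefit.
    """

    intervention: str
    comparator: str
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    cost: dict[str, np.ndarray]
    qalys: dict[str, np.ndarray]
    seed: int | None
    mean_delta_cost: float = field(init=False)
    mean_delta_qalys: float = field(init=False)
    prob_cost_effective: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean_delta_cost = float(self.delta_cost.mean())
        self.mean_delta_qalys = float(self.delta_qalys.mean())

    @property
    def n(self) -> int:
        return self.delta_cost.size


def _sample_beta(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return mean
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ValueError(f"SD {sd} too large for Beta with mean {mean}")
    nu = mean * (1 - mean) / var - 1
    return float(rng.beta(mean * nu, (1 - mean) * nu))


def _sample_gamma(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0 or mean == 0:
        return mean
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return float(rng.gamma(shape, scale))


def _sample_transition_rows(p: np.ndarray, se: np.ndarray | None,
                            default_concentration: float,
                            rng: np.random.Generator) -> np.ndarray:
    out = p.copy()
    for i in range(p.shape[0]):
        support = np.where(p[i] > 0)[0]
        if support.size < 2:
            continue
        if se is not None:
            m = p[i, support]
            j_star = support[np.argmax(p[i, support] * (1 - p[i, support]))]
            s = se[i, j_star]
            if s == 0:
                continue  # degenerate: hold the row fixed
            mj = p[i, j_star]
            nu = mj * (1 - mj) / (s * s) - 1
            if nu <= 0:
                continue
        else:
            nu = default_concentration
        alpha = p[i, support] * nu
        out[i, :] = 0.0
        out[i, support] = rng.dirichlet(alpha)
    return out


def sample_psa_draw(model: DecisionModel, rng: np.random.Generator,
                    default_concentration: float = 100.0) -> PsaDraw:
    """One joint draw of all uncertain parameters, solved deterministically.

    Utilities are arm-specific; medication and diagnostic unit costs are
    shared between arms and drawn once; use probabilities, administration
    cost and doses are held fixed.
    """
    m = model.copy()

    for s in m.strategies:
        for i in range(N_BANDS):
            s.utilities.mean[i] = _sample_beta(
                float(s.utilities.mean[i]), float(s.utilities.sd[i]), rng
            )

    shared_meds = {
        name: _sample_gamma(getattr(model.strategies[0].costs, name).mean,
                            getattr(model.strategies[0].costs, name).sd, rng)
        for name in SHARED_COST_ITEMS
    }
    base_entry = model.strategies[0].costs.entry_items
    shared_entry = tuple(_sample_gamma(it.mean, it.sd, rng) for it in base_entry)
    drug_low = model.intervention.costs.drug_cost_low
    drug_high = model.intervention.costs.drug_cost_high
    drug_cost = (drug_low if drug_low == drug_high
                 else float(rng.uniform(drug_low, drug_high)))

    from dataclasses import replace

    for s in m.strategies:
        for name, value in shared_meds.items():
            item = getattr(s.costs, name)
            setattr(s.costs, name, replace(item, mean=value))
        s.costs.entry_items = tuple(
            replace(it, mean=v) for it, v in zip(s.costs.entry_items, shared_entry)
        )
        if s.drug_active:
            s.costs.drug_cost_per_dose = drug_cost

    for s in m.strategies:
        s.transitions.p = _sample_transition_rows(
            s.transitions.p, s.transitions.se, default_concentration, rng
        )

    res = m.evaluate()
    return PsaDraw(
        cost={name: o.cost for name, o in res.outcomes.items()},
        qalys={name: o.qalys for name, o in res.outcomes.items()},
        delta_cost=res.ce.incremental_cost,
        delta_qalys=res.ce.incremental_qalys,
    )


def run_psa(model: DecisionModel, n: int = 10_000,
            seed: int | None = None,
            default_concentration: float = 100.0) -> PsaResult:
    """``n`` independent joint draws with per-draw substreams spawned from one
    root seed (reproducible regardless of evaluation order)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n)
    names = [s.name for s in model.strategies]
    dc = np.empty(n)
    de = np.empty(n)
    cost = {name: np.empty(n) for name in names}
    qalys = {name: np.empty(n) for name in names}
    for k in range(n):
        draw = sample_psa_draw(model, np.random.default_rng(streams[k]),
                               default_concentration)
        dc[k] = draw.delta_cost
        de[k] = draw.delta_qalys
        for name in names:
            cost[name][k] = draw.cost[name]
            qalys[name][k] = draw.qalys[name]
    result = PsaResult(
        intervention=model.intervention.name,
        comparator=model.comparator.name,
        delta_cost=dc, delta_qalys=de, cost=cost, qalys=qalys, seed=seed,
    )
    for wtp in model.wtp_thresholds:
        result.prob_cost_effective[wtp] = float(np.mean(wtp * de - dc > 0))
    return result


@dataclass
class CeacCurve:
    """Cost-effectiveness acceptability curve for both strategies."""

    thresholds: np.ndarray
    prob_intervention: np.ndarray
    prob_comparator: np.ndarray


def ceac(psa: PsaResult, thresholds: np.ndarray | None = None) -> CeacCurve:
    """Probability each strategy is cost-effective across WTP thresholds.

    At threshold L the intervention wins a draw iff L*dE - dC > 0; ties go
    to the comparator.  Default grid: 0 to 150,000 USD/QALY in 1,000 steps.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 150_000.0, 1001)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid must be non-empty")
    wins = thresholds[:, None] * psa.delta_qalys[None, :] - psa.delta_cost[None, :] > 0
    p_int = wins.mean(axis=1)
    return CeacCurve(thresholds=thresholds, prob_intervention=p_int,
                     prob_comparator=1.0 - p_int)
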