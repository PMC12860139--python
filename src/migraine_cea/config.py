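"""Model configuration: YAML/JSON schema, validation, and model assembly.

A configuration file carries everything a run needs: both strategies'
transition tables (in printed, column-major orientation or already
row-stochastic), utility tables, cost schedules, the horizon, discount rate,
baseline-distribution directive, WTP thresholds and sensitivity-analysis
settings.  ``load_config`` validates the whole document and reports *every*
failing field at once; ``ModelConfig.build_model`` assembles the
:class:`~migraine_cea.model.DecisionModel`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import inputs
from .cohort import TrialProfile, default_trial_profiles, initial_distribution_from_profiles
from .economics import CostItem, CostSchedule, DiscountSpec, UtilitySet
from .markov import InitialDistribution, TransitionMatrix, from_printed_table, normalize_rows
from .model import DecisionModel, StrategyInputs
from .states import BAND_LABELS, DEFAULT_BAND_VALUES, N_BANDS


class ConfigError(ValueError):
    """Raised with the full list of validation failures."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


def default_config() -> dict[str, Any]:
    """The shipped base-case configuration as a plain dict."""

    def utility_map(means, sds):
        return {
            band: {"mean": float(m), "sd": float(s)}
            for band, m, s in zip(BAND_LABELS, means, sds)
        }

    def table_map(table):
        return {
            band: [float(x) for x in row]
            for band, row in zip(BAND_LABELS, np.asarray(table))
        }

    def costs_map(drug_active: bool) -> dict[str, Any]:
        sched = inputs.default_cost_schedule(drug_active)
        return {
            "drug_cost_per_dose": sched.drug_cost_per_dose,
            "drug_cost_low": sched.drug_cost_low,
            "drug_cost_high": sched.drug_cost_high,
            "doses_per_cycle": sched.doses_per_cycle,
            "admin_cost_per_infusion": sched.admin_cost_per_infusion,
            "cm_acute": {"mean": sched.cm_acute.mean, "sd": sched.cm_acute.sd},
            "cm_prevention": {"mean": sched.cm_prevention.mean, "sd": sched.cm_prevention.sd},
            "em_acute": {"mean": sched.em_acute.mean, "sd": sched.em_acute.sd},
            "em_prevention": {"mean": sched.em_prevention.mean, "sd": sched.em_prevention.sd},
            "entry_items": [
                {"name": it.name, "mean": it.mean, "sd": it.sd, "use_prob": it.use_prob}
                for it in sched.entry_items
            ],
        }

    return {
        "horizon": {
            "n_cycles": inputs.N_CYCLES,
            "cycle_length_years": inputs.CYCLE_LENGTH_YEARS,
        },
        "discount_rate": inputs.DISCOUNT_RATE_PER_YEAR,
        "wtp_thresholds": [float(w) for w in inputs.WTP_THRESHOLDS],
        "band_values": [float(v) for v in DEFAULT_BAND_VALUES],
        "initial_distribution": "derive-from-cohort",
        "trials": [
            {
                "name": p.name,
                "baseline_mmd_mean": p.baseline_mmd_mean,
                "mmd_low": p.mmd_low,
                "mmd_high": p.mmd_high,
                "concentration": p.concentration,
                "female_prop": p.female_prop,
                "age_mean": p.age_mean,
                "age_sd": p.age_sd,
                "weight": p.weight,
            }
            for p in default_trial_profiles()
        ],
        "strategies": [
            {
                "name": "eptinezumab",
                "drug_active": True,
                "transitions": {
                    "orientation": "column-major",
                    "table": table_map(inputs.EPTINEZUMAB_TABLE),
                },
                "utilities": utility_map(inputs.EPTINEZUMAB_UTILITY_MEAN,
                                         inputs.EPTINEZUMAB_UTILITY_SD),
                "costs": costs_map(True),
            },
            {
                "name": "placebo",
                "drug_active": False,
                "transitions": {
                    "orientation": "column-major",
                    "table": table_map(inputs.PLACEBO_TABLE),
                },
                "utilities": utility_map(inputs.PLACEBO_UTILITY_MEAN,
                                         inputs.PLACEBO_UTILITY_SD),
                "costs": costs_map(False),
            },
        ],
        "owsa": {
            "utility_multiplier": 0.10,
            "transition_multiplier": 0.10,
            "cost_multiplier": 0.20,
        },
        "psa": {
            "n": 10_000,
            "seed": 1,
            "transition_concentration": inputs.DEFAULT_TRANSITION_CONCENTRATION,
        },
    }


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_utilities(d: Any, where: str, problems: list[str]) -> None:
    if not isinstance(d, dict):
        problems.append(f"{where}: utilities must be a mapping band -> {{mean, sd}}")
        return
    for band in BAND_LABELS:
        if band not in d:
            problems.append(f"{where}: missing utility for band {band!r}")
    for band in d:
        if band not in BAND_LABELS:
            problems.append(f"{where}: unknown band label {band!r}")
    for band, cell in d.items():
        if band not in BAND_LABELS or not isinstance(cell, dict):
            continue
        m = cell.get("mean")
        if not isinstance(m, (int, float)) or not 0 < m < 1:
            problems.append(f"{where}:{band}: utility mean must be in (0, 1)")
        s = cell.get("sd", 0)
        if not isinstance(s, (int, float)) or s < 0:
            problems.append(f"{where}:{band}: utility sd must be >= 0")


def _check_transitions(d: Any, where: str, problems: list[str]) -> None:
    if not isinstance(d, dict) or "table" not in d:
        problems.append(f"{where}: transitions must carry a 'table' mapping")
        return
    orientation = d.get("orientation", "column-major")
    if orientation not in ("column-major", "row-major"):
        problems.append(f"{where}: orientation must be 'column-major' or 'row-major'")
    table = d["table"]
    for band in BAND_LABELS:
        if band not in table:
            problems.append(f"{where}: missing transition row for band {band!r}")
            continue
        row = table[band]
        if not isinstance(row, (list, tuple)) or len(row) != N_BANDS:
            problems.append(f"{where}:{band}: expected {N_BANDS} probabilities")
            continue
        if any(not isinstance(x, (int, float)) or x < 0 or x > 1 for x in row):
            problems.append(f"{where}:{band}: probabilities must be in [0, 1]")
    for band in table:
        if band not in BAND_LABELS:
            problems.append(f"{where}: unknown band label {band!r}")


def _check_costs(d: Any, where: str, problems: list[str]) -> None:
    if not isinstance(d, dict):
        problems.append(f"{where}: costs must be a mapping")
        return
    for key in ("drug_cost_per_dose", "admin_cost_per_infusion"):
        v = d.get(key, 0)
        if not isinstance(v, (int, float)) or v < 0:
            problems.append(f"{where}:{key}: must be a non-negative number")
    for key in ("cm_acute", "cm_prevention", "em_acute", "em_prevention"):
        cell = d.get(key)
        if cell is None:
            problems.append(f"{where}: missing medication cost {key!r}")
            continue
        if cell.get("mean", -1) < 0 or cell.get("sd", 0) < 0:
            problems.append(f"{where}:{key}: mean and sd must be >= 0")
    for i, it in enumerate(d.get("entry_items", [])):
        tag = f"{where}:entry_items[{i}]"
        if it.get("mean", -1) < 0 or it.get("sd", 0) < 0:
            problems.append(f"{tag}: mean and sd must be >= 0")
        if not 0 <= it.get("use_prob", 1.0) <= 1:
            problems.append(f"{tag}: use_prob must be in [0, 1]")


def validate_config(data: dict[str, Any]) -> dict[str, Any]:
    """Validate a configuration dict, reporting every failing field."""
    problems: list[str] = []
    if not isinstance(data, dict):
        raise ConfigError(["configuration root must be a mapping"])

    horizon = data.get("horizon", {})
    if not isinstance(horizon.get("n_cycles", 2), int) or horizon.get("n_cycles", 2) < 1:
        problems.append("horizon:n_cycles must be an integer >= 1")
    if horizon.get("cycle_length_years", 0.25) <= 0:
        problems.append("horizon:cycle_length_years must be positive")
    if data.get("discount_rate", 0.03) < 0:
        problems.append("discount_rate must be >= 0")
    wtp = data.get("wtp_thresholds", [])
    if not wtp or any(w < 0 for w in wtp):
        problems.append("wtp_thresholds must be a non-empty list of values >= 0")

    init = data.get("initial_distribution", "derive-from-cohort")
    if isinstance(init, dict):
        for band in init:
            if band not in BAND_LABELS:
                problems.append(f"initial_distribution: unknown band label {band!r}")
        total = sum(init.get(b, 0.0) for b in BAND_LABELS)
        if abs(total - 1.0) > 1e-6:
            problems.append(f"initial_distribution must sum to 1, got {total}")
    elif init != "derive-from-cohort":
        problems.append(
            "initial_distribution must be 'derive-from-cohort' or a band -> weight mapping"
        )

    strategies = data.get("strategies", [])
    if len(strategies) != 2:
        problems.append("exactly two strategies are required (intervention, comparator)")
    for s in strategies:
        name = s.get("name", "<unnamed>")
        _check_transitions(s.get("transitions"), f"strategies:{name}:transitions", problems)
        _check_utilities(s.get("utilities"), f"strategies:{name}:utilities", problems)
        _check_costs(s.get("costs"), f"strategies:{name}:costs", problems)

    psa = data.get("psa", {})
    if psa.get("n", 1) < 1:
        problems.append("psa:n must be >= 1")

    if problems:
        raise ConfigError(problems)
    return data


# ---------------------------------------------------------------------------
# ModelConfig
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """A validated configuration plus assembly helpers."""

    data: dict[str, Any]

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelConfig":
        return cls(validate_config(data))

    @classmethod
    def default(cls) -> "ModelConfig":
        return cls.from_dict(default_config())

    def to_dict(self) -> dict[str, Any]:
        return self.data

    # -- accessors ---------------------------------------------------------
    @property
    def wtp_thresholds(self) -> tuple[float, ...]:
        return tuple(float(w) for w in self.data["wtp_thresholds"])

    @property
    def psa_settings(self) -> dict[str, Any]:
        return dict(self.data.get("psa", {"n": 10_000, "seed": None,
                                          "transition_concentration": 100.0}))

    @property
    def owsa_multipliers(self) -> dict[str, float]:
        d = self.data.get("owsa", {})
        return {
            "utility": float(d.get("utility_multiplier", 0.10)),
            "transition": float(d.get("transition_multiplier", 0.10)),
            "cost": float(d.get("cost_multiplier", 0.20)),
        }

    def trial_profiles(self) -> tuple[TrialProfile, ...]:
        return tuple(TrialProfile(**t) for t in self.data.get("trials", []))

    def initial_distribution(self) -> InitialDistribution:
        init = self.data.get("initial_distribution", "derive-from-cohort")
        if init == "derive-from-cohort":
            profiles = self.trial_profiles()
            if not profiles:
                raise ConfigError(
                    ["initial_distribution 'derive-from-cohort' requires a trials section"]
                )
            return initial_distribution_from_profiles(profiles)
        weights = np.array([float(init.get(b, 0.0)) for b in BAND_LABELS])
        return InitialDistribution(weights=weights / weights.sum())

    def _strategy(self, s: dict[str, Any]) -> StrategyInputs:
        t = s["transitions"]
        table = np.array([t["table"][band] for band in BAND_LABELS], dtype=float)
        if t.get("orientation", "column-major") == "column-major":
            tm = from_printed_table(table, s["name"])
        else:
            tm = TransitionMatrix(strategy=s["name"], p=normalize_rows(table))
        u = s["utilities"]
        utilities = UtilitySet(
            s["name"],
            [u[b]["mean"] for b in BAND_LABELS],
            [u[b].get("sd", 0.0) for b in BAND_LABELS],
        )
        c = s["costs"]

        def item(key: str) -> CostItem:
            return CostItem(key, c[key]["mean"], c[key].get("sd", 0.0))

        costs = CostSchedule(
            drug_cost_per_dose=c.get("drug_cost_per_dose", 0.0),
            doses_per_cycle=c.get("doses_per_cycle", 1),
            drug_cost_low=c.get("drug_cost_low"),
            drug_cost_high=c.get("drug_cost_high"),
            admin_cost_per_infusion=c.get("admin_cost_per_infusion", 0.0),
            cm_acute=item("cm_acute"),
            cm_prevention=item("cm_prevention"),
            em_acute=item("em_acute"),
            em_prevention=item("em_prevention"),
            entry_items=tuple(
                CostItem(it["name"], it["mean"], it.get("sd", 0.0), it.get("use_prob", 1.0))
                for it in c.get("entry_items", [])
            ),
        )
        return StrategyInputs(s["name"], tm, utilities, costs, bool(s.get("drug_active")))

    def build_model(self) -> DecisionModel:
        horizon = self.data.get("horizon", {})
        model = DecisionModel(
            strategies=[self._strategy(s) for s in self.data["strategies"]],
            init=self.initial_distribution(),
            n_cycles=int(horizon.get("n_cycles", 2)),
            discount=DiscountSpec(
                annual_rate=float(self.data.get("discount_rate", 0.03)),
                cycle_length_years=float(horizon.get("cycle_length_years", 0.25)),
            ),
            wtp_thresholds=self.wtp_thresholds,
        )
        if "band_values" in self.data:
            model.band_values = tuple(float(v) for v in self.data["band_values"])
        return model


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load and validate a YAML/JSON configuration; ``None`` loads the
    shipped base-case default."""
    if path is None:
        return ModelConfig.default()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ModelConfig.from_dict(data)


def dump_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration back to YAML or JSON (round-trip safe)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=False) + "\n")
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
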