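"""CSV/JSON writers for every pipeline stage.

All outputs are plain text with deterministic field ordering so reruns with
the same seed produce byte-identical files.  ICERs at dominated/dominant
bounds are written as explicit sentinels (``dominant``/``dominated``/
``undefined``), never as fabricated numbers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .economics import icer_repr
from .estimation import BootstrapEstimate
from .model import ModelResult
from .sensitivity import CeacCurve, PsaResult, TornadoEntry
from .states import BAND_LABELS


def _ensure_dir(out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def write_trace_csv(result: ModelResult, out_dir: str | Path) -> Path:
    """``trace.csv``: cycle x band occupancy for every strategy."""
    out = _ensure_dir(out_dir)
    rows = []
    for name, o in result.outcomes.items():
        for k, occ in enumerate(o.trace.occupancy):
            rows.append({"strategy": name, "cycle": k,
                         **{band: occ[i] for i, band in enumerate(BAND_LABELS)}})
    path = out / "trace.csv"
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    return path


def write_base_case_csv(result: ModelResult, out_dir: str | Path) -> Path:
    """``base_case.csv``: cost, incremental cost, QALYs, incremental QALYs,
    ICER — one row per strategy, comparator's incremental cells blank."""
    out = _ensure_dir(out_dir)
    ce = result.ce
    rows = [
        {
            "strategy": ce.strategy,
            "mean_cost": f"{result.outcomes[ce.strategy].cost:.2f}",
            "incremental_cost": f"{ce.incremental_cost:.2f}",
            "mean_qalys": f"{result.outcomes[ce.strategy].qalys:.6f}",
            "incremental_qalys": f"{ce.incremental_qalys:.6f}",
            "icer": icer_repr(ce),
            "mmd_change": f"{result.outcomes[ce.strategy].mmd_change:.4f}",
        },
        {
            "strategy": ce.comparator,
            "mean_cost": f"{result.outcomes[ce.comparator].cost:.2f}",
            "incremental_cost": "",
            "mean_qalys": f"{result.outcomes[ce.comparator].qalys:.6f}",
            "incremental_qalys": "",
            "icer": "",
            "mmd_change": f"{result.outcomes[ce.comparator].mmd_change:.4f}",
        },
    ]
    path = out / "base_case.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_tornado_csv(entries: list[TornadoEntry], out_dir: str | Path) -> Path:
    """``tornado.csv``: ICER at each parameter's bounds, widest bar first."""
    out = _ensure_dir(out_dir)
    rows = [
        {
            "parameter": e.parameter,
            "icer_low": e.low_label,
            "icer_high": e.high_label,
            "width": "inf" if np.isinf(e.width) else f"{e.width:.4f}",
        }
        for e in entries
    ]
    path = out / "tornado.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_psa_csv(psa: PsaResult, out_dir: str | Path) -> Path:
    """``psa_draws.csv``: per-draw incremental cost and QALYs (CE plane)."""
    out = _ensure_dir(out_dir)
    df = pd.DataFrame({
        "draw": np.arange(psa.n),
        "delta_cost": psa.delta_cost,
        "delta_qalys": psa.delta_qalys,
        f"cost_{psa.intervention}": psa.cost[psa.intervention],
        f"cost_{psa.comparator}": psa.cost[psa.comparator],
        f"qalys_{psa.intervention}": psa.qalys[psa.intervention],
        f"qalys_{psa.comparator}": psa.qalys[psa.comparator],
    })
    path = out / "psa_draws.csv"
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def write_ceac_csv(curve: CeacCurve, psa: PsaResult, out_dir: str | Path) -> Path:
    """``ceac.csv``: probability each strategy is cost-effective by WTP."""
    out = _ensure_dir(out_dir)
    df = pd.DataFrame({
        "wtp": curve.thresholds,
        f"prob_{psa.intervention}": curve.prob_intervention,
        f"prob_{psa.comparator}": curve.prob_comparator,
    })
    path = out / "ceac.csv"
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def write_transition_csv(estimates: dict[str, BootstrapEstimate],
                         out_dir: str | Path) -> Path:
    """``transition_estimates.csv``: bootstrap mean and SE per arm/from/to."""
    out = _ensure_dir(out_dir)
    rows = []
    for arm in sorted(estimates):
        est = estimates[arm]
        for i, frm in enumerate(BAND_LABELS):
            for j, to in enumerate(BAND_LABELS):
                rows.append({"arm": arm, "from": frm, "to": to,
                             "mean": f"{est.mean[i, j]:.8f}",
                             "se": f"{est.se[i, j]:.8f}"})
    path = out / "transition_estimates.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def config_digest(config_data: dict) -> str:
    """Stable SHA-256 digest of a configuration dict."""
    return hashlib.sha256(
        json.dumps(config_data, sort_keys=True).encode()
    ).hexdigest()[:16]


def write_run_metadata(out_dir: str | Path, *, seed: int | None,
                       config_data: dict, extra: dict | None = None) -> Path:
    """``run_metadata.json``: everything needed to reproduce the run."""
    from . import __version__

    out = _ensure_dir(out_dir)
    meta = {
        "version": __version__,
        "seed": seed,
        "config_sha256": config_digest(config_data),
        "wtp_thresholds": config_data.get("wtp_thresholds"),
    }
    if extra:
        meta.update(extra)
    path = out / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path
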