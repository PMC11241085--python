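"""Report bundles: run all three methods on a cohort and serialize results.

The bundle mirrors the shape of a norms report: per ear and per method, a
sub-group summary table, the fitted link-function parameters, the overall
percentage of ears below the fitted 95% CL, and curve-difference series
between the simulation method and the distribution-free methods on a PTA
grid.  JSON is the canonical machine output (fully regenerable from the
recorded config and seeds); CSV tables are provided for eyeballing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import BUILTIN_SCHEMES, EarRecord, SubgroupSummary
from .curves import CurveParams, fit_nqr
from .evaluation import percent_below
from .harrell_davis import HDConfig, method2_curve
from .simulation import SimulationConfig, method1_curve

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_comparison", "bundle_to_json", "summaries_to_frame"]

FORMAT_VERSION = "1"


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full three-method comparison run."""

    scheme: str = "group1"
    master_seed: int = 0
    n_sims: int = 50_000
    n_boot: int = 1000
    pta_grid_max: float = 90.0
    ears: tuple[str, ...] = ("R", "L")


def _params_dict(p: CurveParams) -> dict:
    d = {k: v for k, v in dataclasses.asdict(p).items() if v is not None}
    return d


def summaries_to_frame(summaries: Sequence[SubgroupSummary]) -> pd.DataFrame:
    """Sub-group summaries as a table shaped like a published norms table."""
    rows = []
    for s in summaries:
        row = {
            "subgroup": s.label, "n": s.n, "mean_pta": s.mean_pta,
            "mean_pbmax": s.mean_pbmax, "sd_pbmax": s.sd_pbmax,
            "skewness": s.skewness, "kurtosis": s.kurtosis,
            "median_pbmax": s.median_pbmax, "cl_95": s.cl_value, "cl_se": s.cl_se,
        }
        row.update(s.extra)
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_comparison(
    records_by_ear: dict[str, list[EarRecord]],
    config: RunConfig | None = None,
) -> dict:
    """Run the simulation, Harrell-Davis and nQR pipelines per ear.

    Returns a JSON-serializable bundle keyed by ear then method, carrying
    sub-group tables, fitted parameters, overall percent-below values, the
    CL curves sampled on a PTA grid, and the config/seeds needed to
    regenerate everything.  A method that fails is reported as an error
    entry without aborting the others.
    """
    if config is None:
        config = RunConfig()
    scheme = BUILTIN_SCHEMES[config.scheme]
    grid = np.arange(0.0, config.pta_grid_max + 1.0, 1.0)
    bundle: dict = {
        "format_version": FORMAT_VERSION,
        "config": dataclasses.asdict(config),
        "ears": {},
    }
    ss = np.random.SeedSequence(config.master_seed)
    for ear in config.ears:
        recs = records_by_ear.get(ear, [])
        ear_out: dict = {"n_ears": len(recs), "methods": {}}
        if not recs:
            logger.warning("no records for ear %s", ear)
            bundle["ears"][ear] = ear_out
            continue
        sim_ss, hd_ss = ss.spawn(2)
        jobs = {
            "simulation": lambda: method1_curve(
                recs, scheme, SimulationConfig(n_sims=config.n_sims, seed=sim_ss)),
            "hd": lambda: method2_curve(
                recs, scheme, HDConfig(n_boot=config.n_boot, seed=hd_ss)),
            "nqr": lambda: (None, fit_nqr(recs, 0.05), fit_nqr(recs, 0.5)),
        }
        for name, job in jobs.items():
            try:
                summaries, cl_curve, center_curve = job()
            except Exception as exc:
                logger.error("method %s failed for ear %s: %s", name, ear, exc)
                ear_out["methods"][name] = {"error": str(exc)}
                continue
            entry = {
                "cl_params": _params_dict(cl_curve),
                "center_params": _params_dict(center_curve),
                "percent_below_cl": percent_below(recs, cl_curve),
                "cl_curve_on_grid": [round(v, 6) for v in np.atleast_1d(cl_curve(grid))],
            }
            if summaries is not None:
                entry["subgroups"] = summaries_to_frame(summaries).to_dict("records")
            ear_out["methods"][name] = entry
        m = ear_out["methods"]
        if "simulation" in m and "error" not in m["simulation"]:
            sim = np.array(m["simulation"]["cl_curve_on_grid"])
            for other in ("hd", "nqr"):
                if other in m and "error" not in m[other]:
                    diff = sim - np.array(m[other]["cl_curve_on_grid"])
                    ear_out.setdefault("cl_differences_vs_simulation", {})[other] = {
                        "pta_grid": list(grid),
                        "diff": [round(v, 6) for v in diff],
                        "rms": float(np.sqrt(np.mean(diff**2))),
                    }
        bundle["ears"][ear] = ear_out
    return bundle


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, float) and math.isnan(o):
        return None
    raise TypeError(f"not JSON-serializable: {type(o)}")


def bundle_to_json(bundle: dict, path: str | Path | None = None) -> str:
    """Canonical JSON rendering (sorted keys, NaN -> null, no timestamps),
    byte-identical across runs with the same config and seed."""
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
            return None
        return obj

    text = json.dumps(clean(bundle), sort_keys=True, indent=1, default=_json_default)
    if path is not None:
        Path(path).write_text(text)
    return text
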