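"""Split-half accuracy/consistency evaluation and grouping sensitivity.

A fitted lower 95% CL curve is judged by the share of independent ears
scoring strictly below it: the target is 5%.  The harness draws repeated
random 50/50 splits of the cohort *by participant* (both ears of a
participant stay together, avoiding paired leakage), fits a method's CL
curve on each fitting half, and measures the percentage of test-half ears
below the curve.  The deviation statistic is

    DEV = 5 - percent_below,

negative when too many ears fall below the curve (the curve sits too high).
Across draws, the mean DEV measures accuracy and the SD of DEV measures
consistency.  A second analysis quantifies how much the sub-group-based
methods depend on the arbitrary choice of PTA bins, as RMS differences
between CL curves fitted under different binning schemes.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .cohort import EarRecord, SubgroupScheme, group_records
from .curves import CurveParams, eval_curve, fit_nqr
from .harrell_davis import HDConfig, method2_curve
from .simulation import SimulationConfig, method1_curve

logger = logging.getLogger(__name__)

__all__ = [
    "DevResult",
    "percent_below",
    "dev_from_percent",
    "split_draw",
    "evaluate_method",
    "grouping_sensitivity",
]

TARGET_PERCENT = 5.0
METHODS = ("simulation", "hd", "nqr")


@dataclass
class DevResult:
    """DEV across repeated 50/50 draws, overall and per PTA sub-group.

    per_draw_dev has one entry per draw; per_subgroup_dev maps bin label to
    a per-draw list with NaN where a draw left the bin empty.  mean_dev is
    the accuracy, sd_dev the consistency.
    """

    method: str
    n_draws: int
    per_draw_dev: list[float]
    per_subgroup_dev: dict[str, list[float]] = field(default_factory=dict)

    @property
    def mean_dev(self) -> float:
        return float(np.mean(self.per_draw_dev))

    @property
    def sd_dev(self) -> float:
        return float(np.std(self.per_draw_dev, ddof=1))

    def subgroup_stats(self) -> dict[str, tuple[float, float]]:
        out = {}
        for label, devs in self.per_subgroup_dev.items():
            arr = np.asarray(devs, dtype=float)
            arr = arr[~np.isnan(arr)]
            if arr.size:
                out[label] = (float(arr.mean()),
                              float(arr.std(ddof=1)) if arr.size > 1 else math.nan)
        return out


def percent_below(records: Sequence[EarRecord], curve) -> float:
    """Percentage of ears whose PB_max lies strictly below the curve at their
    PTA.  ``curve`` is CurveParams or any callable pta -> bound.  Strict
    comparison matters: scores sitting exactly on the limit are not 'below'
    on a 4-point grid."""
    if not records:
        raise ValueError("records must be non-empty")
    pta = np.array([r.pta for r in records], dtype=float)
    scores = np.array([r.pbmax for r in records], dtype=float)
    bound = eval_curve(curve, pta) if isinstance(curve, CurveParams) else np.asarray(curve(pta), float)
    return float(100.0 * np.mean(scores < bound))


def dev_from_percent(pct_below: float) -> float:
    """DEV = 5 - percent_below; negative means the curve overshoots (more
    than 5% of ears below it)."""
    if not 0.0 <= pct_below <= 100.0:
        raise ValueError("percent_below must be in [0, 100]")
    return TARGET_PERCENT - pct_below


def split_draw(
    records: Sequence[EarRecord],
    fraction: float = 0.5,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[list[EarRecord], list[EarRecord]]:
    """One random participant-level split into (fitting, test) sets.

    Participants are shuffled and the first round(fraction * P) go to the
    fitting set with all their ears; the rest form the test set.  Disjoint
    and exhaustive by construction; deterministic given ``seed``.
    """
    by_pid: dict[str, list[EarRecord]] = {}
    for r in records:
        by_pid.setdefault(r.participant_id, []).append(r)
    pids = sorted(by_pid)
    if len(pids) < 2:
        raise ValueError("need at least 2 participants to split")
    n_fit = int(round(fraction * len(pids)))
    if n_fit == 0 or n_fit == len(pids):
        raise ValueError(f"fraction {fraction} leaves an empty fitting or test set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pids))
    fit_pids = {pids[i] for i in order[:n_fit]}
    fitting = [r for r in records if r.participant_id in fit_pids]
    test = [r for r in records if r.participant_id not in fit_pids]
    return fitting, test


def _fit_cl_curve(
    method: str,
    fitting: list[EarRecord],
    scheme: SubgroupScheme,
    seed: np.random.SeedSequence | None,
    n_sims: int,
    n_boot: int,
) -> CurveParams:
    if method == "simulation":
        _, curve, _ = method1_curve(fitting, scheme, SimulationConfig(n_sims=n_sims, seed=seed))
        return curve
    if method == "hd":
        _, curve, _ = method2_curve(fitting, scheme, HDConfig(n_boot=n_boot, seed=seed))
        return curve
    if method == "nqr":
        return fit_nqr(fitting, tau=0.05, compute_gof=False)
    raise ValueError(f"unknown method {method!r}")


def evaluate_method(
    records: Sequence[EarRecord],
    method: str,
    scheme: SubgroupScheme,
    n_draws: int = 25,
    master_seed: int | None = None,
    *,
    fraction: float = 0.5,
    n_sims: int = 50_000,
    n_boot: int = 1000,
    oracle: Callable[[np.ndarray], np.ndarray] | None = None,
    max_failures: int = 5,
) -> DevResult:
    """Accuracy and consistency of one method over repeated 50/50 draws.

    For each draw: split by participant, fit the method's 95% CL curve on
    the fitting half (method "oracle" skips fitting and uses the supplied
    true-quantile callable), then DEV = 5 - percent_below on the test half,
    overall and within each test-half sub-group of ``scheme``.  The nQR
    route ignores the scheme for fitting — bins only stratify the report.
    Bit-reproducible given ``master_seed``.
    """
    records = list(records)
    if method == "oracle" and oracle is None:
        raise ValueError("method 'oracle' needs an oracle callable")
    if method not in METHODS and method != "oracle":
        raise ValueError(f"method must be one of {METHODS} or 'oracle'")
    ss = np.random.SeedSequence(master_seed)
    draw_seeds = ss.spawn(n_draws)
    per_draw: list[float] = []
    per_sub: dict[str, list[float]] = {label: [] for label in scheme.labels}
    n_failed = 0
    for d in range(n_draws):
        split_ss, fit_ss = draw_seeds[d].spawn(2)
        fitting, test = split_draw(records, fraction, split_ss)
        try:
            if method == "oracle":
                curve = oracle
            else:
                curve = _fit_cl_curve(method, fitting, scheme, fit_ss, n_sims, n_boot)
        except Exception as exc:  # a degenerate half-split
            n_failed += 1
            logger.warning("draw %d: fit failed (%s)", d, exc)
            if n_failed > max_failures:
                raise RuntimeError(f"more than {max_failures} draws failed to fit") from exc
            for label in scheme.labels:
                per_sub[label].append(math.nan)
            continue
        per_draw.append(dev_from_percent(percent_below(test, curve)))
        for label, recs in group_records(test, scheme).items():
            per_sub[label].append(
                dev_from_percent(percent_below(recs, curve)) if recs else math.nan
            )
    return DevResult(method=method, n_draws=n_draws,
                     per_draw_dev=per_draw, per_subgroup_dev=per_sub)


def grouping_sensitivity(
    records: Sequence[EarRecord],
    schemes: Sequence[SubgroupScheme],
    method: str = "simulation",
    pta_grid: Sequence[float] | None = None,
    *,
    seed: int | None = None,
    n_sims: int = 50_000,
    n_boot: int = 1000,
) -> list[dict]:
    """Sensitivity of the sub-group methods to the choice of PTA bins.

    Fits the method's CL curve on the full cohort under each scheme and
    compares every scheme against the first over ``pta_grid`` (default
    0..90 dB HL step 1): RMS, max and min signed curve differences in
    percentage points, plus the fitted parameters.
    """
    if len(schemes) < 2:
        raise ValueError("need at least 2 schemes to compare")
    if method not in ("simulation", "hd"):
        raise ValueError("grouping sensitivity applies to the sub-group methods only")
    grid = np.arange(0.0, 91.0, 1.0) if pta_grid is None else np.asarray(pta_grid, float)
    # key the Monte-Carlo stream on the scheme's identity, not its position:
    # listing the same scheme twice must reproduce the same curve exactly
    curves = [
        _fit_cl_curve(
            method, list(records), sch,
            np.random.SeedSequence([0 if seed is None else seed,
                                    zlib.crc32(sch.name.encode())]),
            n_sims, n_boot,
        )
        for sch in schemes
    ]
    ref = eval_curve(curves[0], grid)
    rows = []
    for sch, curve in zip(schemes, curves):
        diff = eval_curve(curve, grid) - ref
        rows.append({
            "scheme": sch.name,
            "vs": schemes[0].name,
            "rms_diff": float(np.sqrt(np.mean(diff**2))),
            "max_diff": float(diff.max()),
            "min_diff": float(diff.min()),
            "params": curve,
        })
    return rows
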