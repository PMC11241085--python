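"""Censored-normal Monte-Carlo estimation of the lower 95% confidence limit.

For each PTA sub-group the method assumes scores are Normal(mean, SD) with
the moments measured in that sub-group, draws 50,000 simulated scores,
clamps them into [0, 100] (values above 100 set to 100, below 0 set to 0 —
censoring, not resampling), takes the empirical 5th percentile, and rounds
it to the nearest multiple of 4 to respect the 25-item score grid.  The
rounded value is the sub-group's lower one-tailed 95% CL (CL_S).

The standard error of CL_S follows the asymptotic order-statistic formula
for a p-quantile at the sub-group's own sample size N (not the simulation
count): SE = sqrt(p(1-p)/N) / f(q_p), with f the fitted normal density.

An historical variant replaces the measured SD with 1.62 times the binomial
SD of a 25-trial proportion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .cohort import (
    EarRecord,
    SubgroupScheme,
    SubgroupSummary,
    group_records,
    round_to_step,
    summarize_subgroup,
)
from .curves import CurveParams, fit_curve_ls

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "SimResult", "simulate_cl_s", "quantile_se", "method1_curve"]

N_ITEMS = 25  # words per list; the score grid is 100/25 = 4%


@dataclass(frozen=True)
class SimulationConfig:
    """Monte-Carlo settings.

    sd_mode "measured" uses the sub-group's sample SD; "binomial_x1.62"
    uses 1.62 * 100 * sqrt(p(1-p)/25) with p = mean/100 (historical
    comparison only).
    """

    n_sims: int = 50_000
    seed: int | np.random.SeedSequence | None = None
    sd_mode: str = "measured"
    score_step: float = 4.0
    quantile_p: float = 0.05

    def __post_init__(self) -> None:
        if self.n_sims < 1000:
            raise ValueError("n_sims must be >= 1000 for a stable extreme percentile")
        if self.sd_mode not in ("measured", "binomial_x1.62"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")
        if not 0.0 < self.quantile_p < 1.0:
            raise ValueError("quantile_p must be in (0, 1)")


@dataclass(frozen=True)
class SimResult:
    """Censored-sample moments and the estimated lower CL for one sub-group."""

    sim_mean: float
    sim_sd: float
    cl_s: float      # rounded to the score grid
    cl_raw: float    # empirical percentile before rounding


def _effective_sd(mean: float, sd: float, config: SimulationConfig) -> float:
    if config.sd_mode == "binomial_x1.62":
        p = mean / 100.0
        return 1.62 * 100.0 * math.sqrt(max(p * (1.0 - p), 0.0) / N_ITEMS)
    return sd


def simulate_cl_s(mean: float, sd: float, config: SimulationConfig | None = None) -> SimResult:
    """Monte-Carlo lower CL for one sub-group from its (mean, SD).

    Draws n_sims from Normal(mean, sd), censors into [0, 100], and takes the
    order statistic at rank ceil(p * n_sims) — the score below which 5% of
    the simulated values fall — then rounds to the score grid.
    """
    if config is None:
        config = SimulationConfig()
    sd = _effective_sd(mean, sd, config)
    if sd < 0 or not math.isfinite(mean):
        raise ValueError("sd must be >= 0 and mean finite")
    if sd == 0.0:
        logger.info("zero SD: degenerate distribution, CL equals the (rounded) mean")
        m = float(np.clip(mean, 0.0, 100.0))
        return SimResult(m, 0.0, float(round_to_step(m, config.score_step)), m)
    rng = np.random.default_rng(config.seed)
    draws = np.clip(rng.normal(mean, sd, config.n_sims), 0.0, 100.0)
    rank = math.ceil(config.quantile_p * config.n_sims)  # "below which 5% fell"
    cl_raw = float(np.partition(draws, rank - 1)[rank - 1])
    return SimResult(
        sim_mean=float(draws.mean()),
        sim_sd=float(draws.std(ddof=1)),
        cl_s=float(round_to_step(cl_raw, config.score_step)),
        cl_raw=cl_raw,
    )


def quantile_se(
    p: float, n_group: int, mean: float, sd: float, *, sample=None
) -> float:
    """Asymptotic SE of the sample p-quantile at group size ``n_group``.

    sqrt(p(1-p)/n) / f(q_p) with f the Normal(mean, sd) density at the
    distribution's p-quantile.  Uses the clinical sub-group's N, not the
    simulation count: the CL's sampling uncertainty comes from the measured
    moments, not the Monte-Carlo noise.  Passing ``sample`` switches to an
    empirical variant: q_p and f are then taken from the sample quantile and
    a Gaussian kernel density estimate instead of the fitted normal.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if n_group < 2:
        raise ValueError("n_group must be >= 2")
    if sample is not None:
        x = np.asarray(sample, dtype=float)
        q_p = float(np.quantile(x, p))
        dens = float(stats.gaussian_kde(x)(q_p)[0])
    else:
        if sd <= 0:
            raise ValueError("sd must be positive")
        q_p = stats.norm.ppf(p, loc=mean, scale=sd)
        dens = stats.norm.pdf(q_p, loc=mean, scale=sd)
    if dens < 1e-300:
        raise ValueError("density underflow at the requested quantile")
    return float(math.sqrt(p * (1.0 - p) / n_group) / dens)


def method1_curve(
    records: list[EarRecord],
    scheme: SubgroupScheme,
    config: SimulationConfig | None = None,
) -> tuple[list[SubgroupSummary], CurveParams, CurveParams]:
    """Full simulation-method pipeline on a cohort.

    Per scheme bin: measured moments -> Monte-Carlo CL_S and censored-sample
    moments -> order-statistic SE; then the link function is least-squares
    fitted to the (mean PTA, CL_S) and (mean PTA, simulated mean) points.
    Bins with fewer than 2 ears are skipped with a warning.  Each bin gets
    its own child seed spawned from the master seed by bin index, so adding
    or dropping a bin leaves the others' draws unchanged.
    """
    if config is None:
        config = SimulationConfig()
    groups = group_records(records, scheme)
    ss = (config.seed if isinstance(config.seed, np.random.SeedSequence)
          else np.random.SeedSequence(config.seed))
    children = ss.spawn(len(scheme.labels))
    summaries: list[SubgroupSummary] = []
    for i, label in enumerate(scheme.labels):
        recs = groups[label]
        if len(recs) < 2:
            logger.warning("bin %s has %d ear(s); skipped", label, len(recs))
            continue
        if len(recs) < 10:
            logger.info("bin %s has only %d ears; estimates may be unstable", label, len(recs))
        summ = summarize_subgroup(recs, label)
        bin_cfg = replace(config, seed=children[i])
        sim = simulate_cl_s(summ.mean_pbmax, summ.sd_pbmax, bin_cfg)
        summ.cl_value = sim.cl_s
        if summ.sd_pbmax > 0:
            summ.cl_se = quantile_se(config.quantile_p, summ.n, summ.mean_pbmax, summ.sd_pbmax)
        summ.extra.update(sim_mean=sim.sim_mean, sim_sd=sim.sim_sd, cl_raw=sim.cl_raw)
        summaries.append(summ)
    pts_cl = [(s.mean_pta, s.cl_value) for s in summaries]
    pts_mean = [(s.mean_pta, s.extra["sim_mean"]) for s in summaries]
    cl_curve = fit_curve_ls(pts_cl)
    mean_curve = fit_curve_ls(pts_mean)
    return summaries, cl_curve, mean_curve
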