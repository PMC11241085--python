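"""The PB_max-vs-PTA link function and its fitting machinery.

All three estimation routes express a score bound as a continuous function of
PTA through the same three-parameter form

    PB_max(PTA) = beta1 * (2 - exp(beta2 * PTA**beta3))

with beta1 the score at PTA = 0 dB HL and beta2, beta3 controlling slope and
curvature.  Negative PTAs evaluate to beta1 and negative function values are
clamped to zero, so the curve is a bounded, non-increasing map from hearing
loss to percent correct.

Two fitting modes are provided: unweighted least squares to per-sub-group
points (for the simulation and Harrell-Davis routes), and nonlinear quantile
regression on raw ear records via the check (pinball) loss, whose minimizer
at level tau is the conditional tau-quantile curve.  The check loss is
non-smooth, so the quantile fit uses derivative-free Nelder-Mead restarts
from a fixed grid of starting points; the fit is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .cohort import EarRecord

__all__ = [
    "CurveParams",
    "eval_curve",
    "fit_curve_ls",
    "check_loss",
    "fit_nqr",
    "r1_goodness",
    "nqr_param_se",
]

# Parameter box: beta1 in (0, 110], beta2 in [0, 1], beta3 in [0, 5].
# The exp() argument is additionally capped to avoid overflow at extreme PTA.
BETA1_MAX = 110.0
BETA2_MAX = 1.0
BETA3_MAX = 5.0
_EXP_CAP = 700.0

#: Fixed multi-start grid spanning the plausible fit range.
_START_BETA1 = (80.0, 90.0, 100.0)
_START_BETA2 = (1e-5, 1e-3, 1e-2)
_START_BETA3 = (1.0, 1.5, 2.2)


@dataclass(frozen=True)
class CurveParams:
    """Fitted link-function parameters.

    ``tau`` is the quantile level for quantile-regression fits and None for
    least-squares fits to sub-group points.  ``gof`` holds R^2 (LS) or
    R^1(tau) (quantile fits) when computed.
    """

    beta1: float
    beta2: float
    beta3: float
    tau: float | None = None
    se_beta1: float | None = None
    se_beta2: float | None = None
    se_beta3: float | None = None
    gof: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.beta1 <= BETA1_MAX):
            raise ValueError(f"beta1 must be in (0, {BETA1_MAX}], got {self.beta1}")
        if self.beta2 < 0 or self.beta3 < 0:
            raise ValueError("beta2 and beta3 must be non-negative")

    def __call__(self, pta):
        return eval_curve(self, pta)


def eval_curve(params: CurveParams, pta) -> np.ndarray | float:
    """Evaluate the link function with its clamping rules.

    PTA < 0 returns beta1 (the curve is anchored there); values the formula
    drives below zero are set to zero.  0**beta3 is taken as 0 for beta3 > 0
    and the beta3 = 0 corner is defined to preserve the PTA = 0 anchor.
    """
    x = np.asarray(pta, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    xp = np.where(x > 0, x, 0.0)
    if params.beta3 == 0.0:
        # x**0 would be 1 everywhere, breaking the beta1 anchor at PTA = 0;
        # define the degenerate curve as flat at beta1.
        y = np.full_like(x, params.beta1)
    else:
        arg = np.minimum(params.beta2 * xp**params.beta3, _EXP_CAP)
        y = params.beta1 * (2.0 - np.exp(arg))
    y = np.where(x < 0, params.beta1, y)
    y = np.maximum(y, 0.0)
    return float(y[0]) if scalar else y


def _eval_raw(b1: float, b2: float, b3: float, x: np.ndarray) -> np.ndarray:
    """eval_curve inlined for the optimizers (x pre-clipped at 0)."""
    arg = np.minimum(b2 * x**b3, _EXP_CAP)
    return np.maximum(b1 * (2.0 - np.exp(arg)), 0.0)


def fit_curve_ls(
    points: Sequence[tuple[float, float]], *, weights: Sequence[float] | None = None
) -> CurveParams:
    """Least-squares fit of the link function to (PTA, value) points.

    Unweighted by default; per-point weights (e.g. sub-group sizes) are
    optional.  Runs bounded trust-region least squares from every point of
    the fixed start grid and keeps the best solution, so the fit is
    deterministic.  Requires >= 4 points spanning >= 30 dB of PTA.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (pta, value) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if len(x) < 4:
        raise ValueError(f"need >= 4 points to fit the curve, got {len(x)}")
    if x.max() - x.min() < 30.0:
        raise ValueError("points must span at least 30 dB of PTA")
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, float))
    xp = np.maximum(x, 0.0)

    def residuals(beta):
        return w * (y - _eval_raw(*beta, xp))

    best = None
    lb = [1e-6, 0.0, 1e-6]
    ub = [BETA1_MAX, BETA2_MAX, BETA3_MAX]
    for b1 in _START_BETA1:
        for b2 in _START_BETA2:
            for b3 in _START_BETA3:
                try:
                    sol = optimize.least_squares(
                        residuals, [b1, b2, b3], bounds=(lb, ub),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                    )
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
    if best is None:
        raise RuntimeError("curve fit failed from every start point")
    ss_res = float(np.sum((y - _eval_raw(*best.x, xp)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else math.nan)
    b1, b2, b3 = best.x
    return CurveParams(beta1=float(b1), beta2=float(b2), beta3=float(b3), gof=r2)


def check_loss(residual, tau: float):
    """Check (pinball) loss rho_tau(r) = r * (tau - 1[r < 0]).

    Its expected-loss minimizer is the tau-quantile; summing it over
    residuals is the quantile-regression objective.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    r = np.asarray(residual, dtype=float)
    out = r * (tau - (r < 0))
    return float(out) if np.ndim(residual) == 0 else out


_LOG_B2_MIN, _LOG_B2_MAX = -9.0, 0.0


def _total_check_loss(
    u: np.ndarray, x: np.ndarray, y: np.ndarray, tau: float, huber_width: float = 0.0
) -> float:
    """Objective in (beta1, log10 beta2, beta3) space with soft box penalty.

    huber_width > 0 replaces |r| with a quadratic of matching slope inside
    [-w, w], smoothing the kink at zero residual (optional stabilizer for
    gradient-based refinement; off by default).
    """
    b1, lb2, b3 = u
    pen = 0.0
    for v, lo, hi in ((b1, 1e-3, BETA1_MAX), (lb2, _LOG_B2_MIN, _LOG_B2_MAX), (b3, 1e-3, BETA3_MAX)):
        if v < lo:
            pen += (lo - v) ** 2
        elif v > hi:
            pen += (v - hi) ** 2
    b1 = min(max(b1, 1e-3), BETA1_MAX)
    lb2 = min(max(lb2, _LOG_B2_MIN), _LOG_B2_MAX)
    b3 = min(max(b3, 1e-3), BETA3_MAX)
    resid = y - _eval_raw(b1, 10.0**lb2, b3, x)
    if huber_width > 0.0:
        w = huber_width
        absr = np.abs(resid)
        mag = np.where(absr <= w, resid**2 / (2 * w) + w / 2, absr)
        loss = float(np.sum(mag * np.where(resid >= 0, tau, 1.0 - tau)))
    else:
        loss = float(np.sum(resid * (tau - (resid < 0))))
    return loss + 1e6 * pen


def _nm(u0, args, maxiter=3000):
    return optimize.minimize(
        _total_check_loss, u0, args=args, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": maxiter, "maxfev": maxiter},
    )


def fit_nqr(
    records: Sequence[EarRecord],
    tau: float,
    *,
    compute_gof: bool = True,
    huber_width: float = 0.0,
) -> CurveParams:
    """Nonlinear quantile regression of PB_max on PTA at level ``tau``.

    Minimizes the summed check loss of the link function over raw ear
    records — no sub-grouping.  beta2 is optimized on a log10 scale (its
    plausible range spans several decades); each start from the fixed grid
    is polished by a second Nelder-Mead pass, and the best start wins.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    if not records:
        raise ValueError("no records to fit")
    x = np.array([r.pta for r in records], dtype=float)
    y = np.array([r.pbmax for r in records], dtype=float)
    if len(records) < 50 or (x.max() - x.min()) < 40.0:
        import logging
        logging.getLogger(__name__).warning(
            "quantile fit on %d records spanning %.0f dB; estimates may be unstable",
            len(records), x.max() - x.min(),
        )
    if np.ptp(y) == 0.0:
        # flat data: the tau-quantile curve is that constant
        import logging
        logging.getLogger(__name__).warning("all scores equal; returning a flat curve")
        return CurveParams(beta1=float(y[0]), beta2=0.0, beta3=1.0, tau=tau, gof=None)
    xp = np.maximum(x, 0.0)
    args = (xp, y, tau, huber_width)

    best = None
    for b1 in _START_BETA1:
        for b2 in _START_BETA2:
            for b3 in _START_BETA3:
                sol = _nm([b1, math.log10(b2), b3], args, maxiter=1500)
                if best is None or sol.fun < best.fun:
                    best = sol
    # polish the winner: a restarted simplex escapes premature collapse
    for _ in range(2):
        sol = _nm(best.x, args)
        if sol.fun <= best.fun:
            best = sol
    b1, lb2, b3 = best.x
    b1 = min(max(b1, 1e-3), BETA1_MAX)
    b3 = min(max(b3, 0.0), BETA3_MAX)
    params = CurveParams(
        beta1=float(b1), beta2=float(10.0 ** min(max(lb2, _LOG_B2_MIN), _LOG_B2_MAX)),
        beta3=float(b3), tau=tau,
    )
    if compute_gof:
        params = replace(params, gof=r1_goodness(records, params, tau))
    return params


def r1_goodness(records: Sequence[EarRecord], params: CurveParams, tau: float) -> float:
    """R^1(tau): one minus the ratio of the fitted model's total check loss
    to that of the constant sample-tau-quantile model — the quantile analog
    of R^2; 1 is a perfect fit, 0 no better than the unconditional quantile.
    """
    x = np.array([r.pta for r in records], dtype=float)
    y = np.array([r.pbmax for r in records], dtype=float)
    fitted = np.sum(check_loss(y - eval_curve(params, x), tau))
    null = np.sum(check_loss(y - np.quantile(y, tau), tau))
    if null == 0.0:
        return math.nan  # degenerate: all scores equal
    return float(1.0 - fitted / null)


def nqr_param_se(
    records: Sequence[EarRecord],
    tau: float,
    n_boot: int = 200,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Bootstrap standard errors of the quantile-fit parameters.

    Resamples participants (both ears of a participant move together) with
    replacement, refits from the full-data solution, and reports the SD of
    each parameter across resamples.  Reproducible given ``seed``.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable parameter SEs")
    full = fit_nqr(records, tau, compute_gof=False)
    by_pid: dict[str, list[EarRecord]] = {}
    for r in records:
        by_pid.setdefault(r.participant_id, []).append(r)
    pids = sorted(by_pid)
    rng = np.random.default_rng(seed)
    u_full = [full.beta1, math.log10(max(full.beta2, 10.0**_LOG_B2_MIN)), full.beta3]
    draws = []
    n_fail = 0
    for _ in range(n_boot):
        chosen = rng.choice(len(pids), size=len(pids), replace=True)
        sample = [rec for i in chosen for rec in by_pid[pids[i]]]
        x = np.maximum(np.array([r.pta for r in sample]), 0.0)
        y = np.array([float(r.pbmax) for r in sample])
        try:
            sol = _nm(u_full, (x, y, tau), maxiter=1000)
            b1, lb2, b3 = sol.x
            draws.append((b1, 10.0 ** min(max(lb2, _LOG_B2_MIN), _LOG_B2_MAX), b3))
        except Exception:
            n_fail += 1
    if n_fail > 0.2 * n_boot:
        raise RuntimeError(f"{n_fail}/{n_boot} bootstrap refits failed")
    arr = np.asarray(draws)
    ses = arr.std(axis=0, ddof=1)
    return float(ses[0]), float(ses[1]), float(ses[2])
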