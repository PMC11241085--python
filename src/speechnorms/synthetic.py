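"""Synthetic audiometric cohorts with analytically known conditional quantiles.

No public dataset pairs PB_max with PTA at the per-ear level, so validation
of the confidence-limit estimators runs on generated cohorts whose true
conditional quantiles are available in closed form.  The generator emulates
the empirical structure of clinical word-score data: a ceiling at 100%,
left-skewed scores at low PTA, conditional SD growing with PTA, scores
discretized to multiples of 4 (25-item lists), and a PTA distribution
matching published clinic sub-group counts.

Two conditional families are provided:

``censored_normal``
    Latent score ~ Normal(mu(PTA), sigma(PTA)), clamped into [0, 100].  This
    is exactly the distributional assumption of the simulation-based CL
    method, making that method unbiased by construction — a useful null.

``skewed_beta``
    Score = 100 * Beta(a, b) with (a, b) moment-matched to (mu, sigma).
    Bounded support and strong left skew at high means mimic real score
    distributions and violate normality, the regime where distribution-free
    estimators earn their keep.

Default calibration (means, SDs, PTA bin weights) follows the published
right/left-ear sub-group tables of a 642-participant sensorineural-loss
cohort; mu and sigma are linearly interpolated between sub-group centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import EarRecord, round_to_step

__all__ = ["CohortModel", "default_model", "gen_cohort", "true_quantile"]

PTA_GRID_STEP = 1.25  # audiometric 5-dB steps averaged over 4 frequencies

# (bin low, bin high, count, mean PTA, mean PB_max, SD PB_max) per sub-group,
# right and left ears; measured-data columns of the published tables.
_CALIBRATION = {
    "R": [
        (0.0, 15.5, 151, 10.2, 96.2, 5.6),
        (15.5, 25.5, 115, 20.8, 93.0, 8.9),
        (25.5, 35.5, 96, 30.1, 89.9, 8.4),
        (35.5, 45.5, 91, 40.8, 84.3, 13.2),
        (45.5, 55.5, 69, 50.7, 81.2, 14.4),
        (55.5, 65.5, 58, 60.2, 72.3, 15.3),
        (65.5, 75.5, 32, 70.8, 50.8, 21.7),
        (75.5, 85.5, 14, 81.3, 44.6, 23.5),
        (85.5, 100.0, 16, 91.2, 21.6, 20.5),
    ],
    "L": [
        (0.0, 15.5, 126, 12.1, 96.2, 5.5),
        (15.5, 25.5, 147, 19.9, 93.9, 7.8),
        (25.5, 35.5, 104, 30.3, 90.1, 9.3),
        (35.5, 45.5, 83, 40.8, 85.8, 11.8),
        (45.5, 55.5, 84, 50.6, 80.4, 14.7),
        (55.5, 65.5, 48, 61.2, 69.3, 18.0),
        (65.5, 75.5, 16, 70.6, 61.6, 16.2),
        (75.5, 85.5, 18, 80.7, 42.8, 15.6),
        (85.5, 100.0, 15, 91.3, 21.7, 22.9),
    ],
}


@dataclass(frozen=True)
class CohortModel:
    """Conditional law of PB_max given PTA plus the PTA mixture.

    mean/sd curves are tabulated at ``curve_pta`` and linearly interpolated
    (flat extrapolation at the ends).  ``pta_bins`` are (low, high, weight)
    triples; PTA is drawn bin-weighted, uniform within bin, snapped to the
    1.25-dB grid.  ``pta_range`` is the supported domain; sampling outside
    it is an error.
    """

    curve_pta: tuple[float, ...]
    curve_sd: tuple[float, ...]
    curve_mean: tuple[float, ...] | None = None
    mean_params: "CurveParams | None" = None  # link-form mean instead of a table
    pta_bins: tuple[tuple[float, float, float], ...] = ((0.0, 100.0, 1.0),)
    family: str = "skewed_beta"
    discretize: bool = True
    pta_range: tuple[float, float] = (0.0, 100.0)
    ear_correlation: float = 0.0  # latent cross-ear correlation; 0 = i.i.d.

    def __post_init__(self) -> None:
        if self.family not in ("censored_normal", "skewed_beta"):
            raise ValueError(f"unknown family {self.family!r}")
        if (self.curve_mean is None) == (self.mean_params is None):
            raise ValueError("provide exactly one of curve_mean or mean_params")
        if self.curve_mean is not None and len(self.curve_pta) != len(self.curve_mean):
            raise ValueError("curve_pta and curve_mean must have equal length")
        if len(self.curve_pta) != len(self.curve_sd):
            raise ValueError("curve_pta and curve_sd must have equal length")
        if any(s <= 0 for s in self.curve_sd):
            raise ValueError("sd curve must be positive everywhere")
        weights = [w for _, _, w in self.pta_bins]
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("pta_bins weights must be non-negative with at least one positive")
        if not -1.0 < self.ear_correlation < 1.0:
            raise ValueError("ear_correlation must be in (-1, 1)")

    def mean_at(self, pta) -> np.ndarray:
        if self.mean_params is not None:
            from .curves import eval_curve

            return np.asarray(eval_curve(self.mean_params, pta))
        return np.interp(pta, self.curve_pta, self.curve_mean)

    def sd_at(self, pta) -> np.ndarray:
        return np.interp(pta, self.curve_pta, self.curve_sd)


def default_model(
    ear: str = "R",
    family: str = "skewed_beta",
    discretize: bool = True,
) -> CohortModel:
    """Model calibrated to the published sub-group moments for one ear."""
    rows = _CALIBRATION[ear.upper()]
    return CohortModel(
        curve_pta=tuple(r[3] for r in rows),
        curve_mean=tuple(r[4] for r in rows),
        curve_sd=tuple(r[5] for r in rows),
        pta_bins=tuple((r[0], r[1], float(r[2])) for r in rows),
        family=family,
        discretize=discretize,
    )


def _beta_ab(mean: np.ndarray, sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Moment-matched Beta shape parameters on the [0, 100] scale.

    Where the requested variance exceeds the Beta bound m(1-m) it is shrunk
    to 99% of the bound (keeps the mean, caps the SD).
    """
    m = np.clip(np.asarray(mean, float) / 100.0, 1e-4, 1.0 - 1e-4)
    v = (np.asarray(sd, float) / 100.0) ** 2
    v = np.minimum(v, 0.99 * m * (1.0 - m))
    k = m * (1.0 - m) / v - 1.0
    return m * k, (1.0 - m) * k


def _sample_pta(model: CohortModel, n: int, rng: np.random.Generator) -> np.ndarray:
    lows = np.array([b[0] for b in model.pta_bins])
    highs = np.array([b[1] for b in model.pta_bins])
    w = np.array([b[2] for b in model.pta_bins], dtype=float)
    idx = rng.choice(len(w), size=n, p=w / w.sum())
    pta = rng.uniform(lows[idx], highs[idx])
    return np.round(pta / PTA_GRID_STEP) * PTA_GRID_STEP


def _conditional_scores(
    model: CohortModel, pta: np.ndarray, z: np.ndarray
) -> np.ndarray:
    """Map standard-normal latents to conditional scores at each PTA."""
    mu = model.mean_at(pta)
    sd = model.sd_at(pta)
    if model.family == "censored_normal":
        scores = np.clip(mu + sd * z, 0.0, 100.0)
    else:
        a, b = _beta_ab(mu, sd)
        scores = 100.0 * stats.beta.ppf(stats.norm.cdf(z), a, b)
    if model.discretize:
        scores = round_to_step(scores, 4.0)
    return scores


def gen_cohort(
    n_participants: int, model: CohortModel | None = None, seed: int | None = None
) -> list[EarRecord]:
    """Generate a cohort of ``n_participants``, two ear records (L, R) each.

    Each ear draws its own PTA from the bin-weighted mixture and a score
    from the conditional family at that PTA; scores are censored into
    [0, 100] (clamped, never resampled) and, when the model discretizes,
    rounded to multiples of 4.  A nonzero ``ear_correlation`` couples the
    two ears' latent normals; the default is independent ears.
    Deterministic given ``seed``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if model is None:
        model = default_model()
    rng = np.random.default_rng(seed)
    pta = {"L": _sample_pta(model, n_participants, rng),
           "R": _sample_pta(model, n_participants, rng)}
    lo, hi = model.pta_range
    for side in ("L", "R"):
        bad = (pta[side] < lo) | (pta[side] > hi)
        if bad.any():
            raise ValueError(
                f"sampled PTA outside the model's supported range [{lo}, {hi}] dB HL"
            )
    z_l = rng.standard_normal(n_participants)
    z_ind = rng.standard_normal(n_participants)
    rho = model.ear_correlation
    z_r = rho * z_l + math.sqrt(1.0 - rho**2) * z_ind
    scores = {"L": _conditional_scores(model, pta["L"], z_l),
              "R": _conditional_scores(model, pta["R"], z_r)}
    records: list[EarRecord] = []
    width = len(str(n_participants))
    for i in range(n_participants):
        pid = f"S{i + 1:0{width}d}"
        for side in ("L", "R"):
            records.append(
                EarRecord(pid, side, float(pta[side][i]), float(scores[side][i]))
            )
    return records


def true_quantile(model: CohortModel, pta, tau: float):
    """Exact conditional tau-quantile of the latent-then-censored law at a
    given PTA (before any discretization) — the oracle every estimator is
    judged against.

    censored_normal: clamp(mu + sigma * z_tau, 0, 100); clamping is monotone
    so quantiles commute with it.  skewed_beta: 100 * Beta inverse CDF.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    p = np.asarray(pta, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    mu = model.mean_at(p)
    sd = model.sd_at(p)
    if model.family == "censored_normal":
        q = np.clip(mu + sd * stats.norm.ppf(tau), 0.0, 100.0)
    else:
        a, b = _beta_ab(mu, sd)
        q = 100.0 * stats.beta.ppf(tau, a, b)
    return float(q[0]) if scalar else q
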