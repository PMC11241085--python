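"""Link-function evaluation, least-squares and quantile fits, R1, SEs."""

import itertools
import math

import numpy as np
import pytest

import speechnorms as sn
from speechnorms.curves import CurveParams, _total_check_loss


class TestEvalCurve:
    def test_anchored_at_beta1_for_zero_and_negative_pta(self):
        p = CurveParams(beta1=88.8, beta2=0.00216, beta3=1.29)
        assert sn.eval_curve(p, 0.0) == pytest.approx(88.8)
        assert sn.eval_curve(p, -10.0) == pytest.approx(88.8)

    def test_hand_evaluation(self):
        # beta1*(2 - exp(beta2 * pta^beta3)) at the fitted-mean parameters
        p = CurveParams(beta1=96.3, beta2=0.0000312, beta3=2.17)
        assert sn.eval_curve(p, 10.2) == pytest.approx(95.83, abs=0.05)

    def test_negative_values_clamped_to_zero(self):
        p = CurveParams(beta1=90.0, beta2=0.01, beta3=1.5)
        assert sn.eval_curve(p, 120.0) == 0.0

    def test_beta3_zero_degenerates_to_flat_beta1(self):
        p = CurveParams(beta1=75.0, beta2=0.5, beta3=0.0)
        assert np.allclose(sn.eval_curve(p, np.array([0.0, 10.0, 50.0])), 75.0)

    def test_continuous_and_nonincreasing_for_positive_params(self):
        p = CurveParams(beta1=95.0, beta2=0.002, beta3=1.4)
        grid = np.linspace(-5, 120, 2000)
        y = sn.eval_curve(p, grid)
        assert np.all(np.diff(y) <= 1e-9)          # non-increasing
        assert np.max(np.abs(np.diff(y))) < 1.0    # no jumps on a dense grid

    def test_parameter_bounds_enforced(self):
        with pytest.raises(ValueError):
            CurveParams(beta1=0.0, beta2=0.001, beta3=1.0)
        with pytest.raises(ValueError):
            CurveParams(beta1=90.0, beta2=-0.1, beta3=1.0)


class TestFitCurveLS:
    def test_exact_recovery_of_generating_parameters(self):
        true = CurveParams(beta1=90.0, beta2=0.001, beta3=1.5)
        pts = [(x, sn.eval_curve(true, x)) for x in (10, 25, 40, 55, 70, 85)]
        fit = sn.fit_curve_ls(pts)
        assert fit.beta1 == pytest.approx(90.0, rel=1e-4)
        assert fit.beta2 == pytest.approx(0.001, rel=1e-4)
        assert fit.beta3 == pytest.approx(1.5, rel=1e-4)
        assert fit.gof == pytest.approx(1.0, abs=1e-10)

    def test_single_perturbed_point_degrades_r2_not_the_anchor(self):
        true = CurveParams(beta1=90.0, beta2=0.001, beta3=1.5)
        pts = [(x, sn.eval_curve(true, x)) for x in (10, 25, 40, 55, 70, 85)]
        pts[2] = (pts[2][0], pts[2][1] + 1.0)
        fit = sn.fit_curve_ls(pts)
        assert fit.gof < 1.0
        assert fit.beta1 == pytest.approx(90.0, abs=2.0)

    def test_constant_ceiling_points_fit_flat(self):
        fit = sn.fit_curve_ls([(x, 100.0) for x in (5, 20, 40, 60, 80)])
        assert fit.beta1 == pytest.approx(100.0, abs=0.1)
        assert sn.eval_curve(fit, 45.0) == pytest.approx(100.0, abs=0.1)

    def test_preconditions(self):
        with pytest.raises(ValueError, match=">= 4 points"):
            sn.fit_curve_ls([(10, 90), (20, 85), (30, 80)])
        with pytest.raises(ValueError, match="span"):
            sn.fit_curve_ls([(10, 90), (15, 88), (20, 85), (25, 80)])


@pytest.mark.parametrize(
    "residual, tau, expected",
    [(1.0, 0.05, 0.05), (-1.0, 0.05, 0.95), (0.0, 0.5, 0.0), (2.0, 0.5, 1.0)],
)
def test_check_loss(residual, tau, expected):
    assert sn.check_loss(residual, tau) == pytest.approx(expected)


class TestFitNQR:
    @pytest.mark.parametrize("tau", [0.05, 0.5])
    def test_noise_free_interpolation_recovers_curve(self, tau, oncurve_records):
        true, records = oncurve_records
        fit = sn.fit_nqr(records, tau, compute_gof=False)
        assert fit.beta1 == pytest.approx(true.beta1, rel=1e-3)
        assert fit.beta2 == pytest.approx(true.beta2, rel=1e-3)
        assert fit.beta3 == pytest.approx(true.beta3, rel=1e-3)

    def test_oracle_recovery_on_censored_normal_cohort(self, smooth_normal_model):
        records = sn.gen_cohort(2500, smooth_normal_model, seed=23)
        fit = sn.fit_nqr(records, 0.05, compute_gof=False)
        grid = np.arange(10.0, 71.0, 5.0)
        err = sn.eval_curve(fit, grid) - sn.true_quantile(smooth_normal_model, grid, 0.05)
        assert np.max(np.abs(err)) < 3.0

    def test_quantile_coverage_of_fitting_records(self, skewed_cohort):
        fit = sn.fit_nqr(skewed_cohort, 0.05, compute_gof=False)
        frac = np.mean([r.pbmax < sn.eval_curve(fit, r.pta) for r in skewed_cohort])
        assert 0.03 <= frac <= 0.07

    def test_lower_quantile_curve_stays_below_median_curve(self, skewed_cohort):
        lo = sn.fit_nqr(skewed_cohort, 0.05, compute_gof=False)
        med = sn.fit_nqr(skewed_cohort, 0.5, compute_gof=False)
        ptas = np.array(sorted({r.pta for r in skewed_cohort}))
        assert np.all(sn.eval_curve(lo, ptas) <= sn.eval_curve(med, ptas) + 1e-6)

    def test_flat_data_returns_flat_curve(self):
        records = [sn.EarRecord(f"p{i}", "R", float(i), 96.0) for i in range(60)]
        fit = sn.fit_nqr(records, 0.05)
        assert fit.beta1 == 96.0 and fit.beta2 == 0.0

    def test_local_optimality_of_check_loss(self, skewed_cohort):
        # nudging any parameter by +/-1% must not beat the optimizer
        fit = sn.fit_nqr(skewed_cohort, 0.05, compute_gof=False)
        x = np.maximum(np.array([r.pta for r in skewed_cohort]), 0.0)
        y = np.array([r.pbmax for r in skewed_cohort])
        u0 = np.array([fit.beta1, math.log10(fit.beta2), fit.beta3])
        base = _total_check_loss(u0, x, y, 0.05)
        for i, sign in itertools.product(range(3), (-1, 1)):
            u = u0.copy()
            if i == 1:  # perturb beta2 itself, not its log
                u[1] = math.log10(fit.beta2 * (1 + 0.01 * sign))
            else:
                u[i] *= 1 + 0.01 * sign
            assert _total_check_loss(u, x, y, 0.05) >= base - 1e-3 * abs(base)

    def test_huberized_loss_gives_nearby_fit(self, oncurve_records):
        true, records = oncurve_records
        smooth = sn.fit_nqr(records, 0.5, compute_gof=False, huber_width=1e-3)
        assert smooth.beta1 == pytest.approx(true.beta1, rel=1e-2)
        assert smooth.beta3 == pytest.approx(true.beta3, rel=1e-2)

    def test_grid_search_oracle_on_tiny_instance(self):
        # exhaustive coarse grid must not beat the optimizer on <= 12 records
        rng = np.random.default_rng(8)
        pta = rng.uniform(5, 85, 12)
        true = CurveParams(beta1=92.0, beta2=0.002, beta3=1.3)
        records = [
            sn.EarRecord(f"p{i}", "R", float(p),
                         float(np.clip(sn.eval_curve(true, p) + rng.normal(0, 8), 0, 100)))
            for i, p in enumerate(pta)
        ]
        tau = 0.3
        fit = sn.fit_nqr(records, tau, compute_gof=False)
        x = np.maximum(pta, 0.0)
        y = np.array([r.pbmax for r in records])
        fit_loss = _total_check_loss(
            [fit.beta1, math.log10(max(fit.beta2, 1e-9)), fit.beta3], x, y, tau)
        grid_losses = [
            _total_check_loss([b1, lb2, b3], x, y, tau)
            for b1 in np.linspace(60, 105, 12)
            for lb2 in np.linspace(-6, -1, 12)
            for b3 in np.linspace(0.5, 3.0, 12)
        ]
        assert fit_loss <= min(grid_losses) + 1e-6


class TestR1:
    def test_perfect_fit_scores_one(self, oncurve_records):
        true, records = oncurve_records
        assert sn.r1_goodness(records, true, 0.05) == pytest.approx(1.0, abs=1e-12)

    def test_null_model_scores_zero(self, skewed_cohort):
        # a flat curve at the sample tau-quantile is exactly the null model
        tau = 0.05
        q = float(np.quantile([r.pbmax for r in skewed_cohort], tau))
        null = CurveParams(beta1=q, beta2=0.0, beta3=1.0)
        assert sn.r1_goodness(skewed_cohort, null, tau) == pytest.approx(0.0, abs=1e-12)

    def test_plausible_band_on_realistic_cohort(self, skewed_cohort):
        fit = sn.fit_nqr(skewed_cohort, 0.05)
        assert 0.5 < fit.gof < 0.95

    def test_degenerate_all_equal_scores(self):
        records = [sn.EarRecord(f"p{i}", "R", float(i), 80.0) for i in range(10)]
        p = CurveParams(beta1=80.0, beta2=0.0, beta3=1.0)
        assert math.isnan(sn.r1_goodness(records, p, 0.05))


class TestParamSE:
    def test_noise_free_data_gives_near_zero_ses(self, oncurve_records):
        _, records = oncurve_records
        ses = sn.nqr_param_se(records, 0.5, n_boot=200, seed=1)
        assert ses[0] < 0.5 and ses[2] < 0.05

    def test_seeded_reproducibility(self, skewed_cohort):
        sub = skewed_cohort[:300]
        a = sn.nqr_param_se(sub, 0.5, n_boot=200, seed=5)
        b = sn.nqr_param_se(sub, 0.5, n_boot=200, seed=5)
        assert a == b

    def test_beta1_se_comparable_to_jackknife(self):
        model = sn.default_model("R", "skewed_beta")
        records = sn.gen_cohort(100, model, seed=31)
        boot_se = sn.nqr_param_se(records, 0.5, n_boot=200, seed=3)[0]
        # grouped delete-one jackknife over participants
        by_pid = {}
        for r in records:
            by_pid.setdefault(r.participant_id, []).append(r)
        pids = sorted(by_pid)
        estimates = []
        for drop in pids:
            sub = [r for pid in pids if pid != drop for r in by_pid[pid]]
            estimates.append(sn.fit_nqr(sub, 0.5, compute_gof=False).beta1)
        n = len(pids)
        jack_se = math.sqrt((n - 1) / n * np.sum((np.array(estimates) - np.mean(estimates)) ** 2))
        assert 0.5 <= boot_se / jack_se <= 2.0
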