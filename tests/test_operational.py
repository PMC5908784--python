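"""Operational-model fitting, expression correction, and affinity deltas."""

import numpy as np
import pytest
from scipy.optimize import brentq, curve_fit

from ctrpharm.datatypes import ExpressionRecord, GroundTruth, OperationalParams, PlateLayout
from ctrpharm.operational import (
    correct_tau,
    correlate_affinities,
    delta_vs_wt,
    fit_operational,
    normalize_expression,
    operational_response,
    predict_ec50,
)
from ctrpharm.synthetic import simulate_crc


def simulate_fit(pKA, log_tau, seed, sd_frac=0.05, **fit_kw):
    truth = GroundTruth(
        operational={("L", "P"): OperationalParams(pKA=pKA, log_tau=log_tau)},
        sd_frac=sd_frac,
    )
    curve = simulate_crc(truth, PlateLayout(), seed, ligand="L", pathway="P")
    return fit_operational([curve], **fit_kw)[0]


class TestPredictEc50:
    def test_null_efficacy_limit(self):
        assert predict_ec50(9.0, -6.0) == pytest.approx(9.0, abs=1e-5)

    def test_reference_value(self):
        # pK_A 9.54, log tau 0.18, n=1 -> pEC50 = 9.54 + log10(1 + 10^0.18)
        assert predict_ec50(9.54, 0.18) == pytest.approx(9.54 + np.log10(1 + 10 ** 0.18))
        assert predict_ec50(9.54, 0.18) == pytest.approx(9.9403, abs=1e-4)

    def test_n2_tau1_closed_form(self):
        ka = 10.0 ** -8.0
        assert 10.0 ** -predict_ec50(8.0, 0.0, n=2.0) == pytest.approx(
            ka / (np.sqrt(3.0) - 1.0), rel=1e-12)

    def test_invalid_slope(self):
        with pytest.raises(ValueError):
            predict_ec50(9.0, 0.0, n=0.0)


class TestFitOperational:
    def test_noiseless_exact_recovery(self):
        fit = simulate_fit(9.54, 0.18, seed=1, sd_frac=0.0)
        assert fit.pKA == pytest.approx(9.54, rel=1e-6)
        assert fit.log_tau == pytest.approx(0.18, rel=1e-6)

    def test_fitted_half_max_matches_closed_form_ec50(self):
        """Numerical half-max of the fitted curve equals the analytic EC50."""
        for seed in range(5):
            fit = simulate_fit(9.2, 0.4, seed=seed)
            assert fit.converged
            plateau = operational_response(1.0, fit.pKA, fit.log_tau, fit.Em, fit.basal, fit.n)
            half = fit.basal + (plateau - fit.basal) / 2.0
            ec50_num = brentq(
                lambda a: operational_response(a, fit.pKA, fit.log_tau, fit.Em,
                                               fit.basal, fit.n) - half,
                1e-16, 1.0, xtol=1e-18, rtol=1e-12,
            )
            assert ec50_num == pytest.approx(10.0 ** -predict_ec50(
                fit.pKA, fit.log_tau, fit.n), rel=1e-6)

    def test_reparameterization_consistency(self):
        """Fitting on linear K_A reproduces the log-scale pK_A estimate."""
        truth = GroundTruth(
            operational={("L", "P"): OperationalParams(pKA=9.0, log_tau=0.3)},
            sd_frac=0.05,
        )
        curve = simulate_crc(truth, PlateLayout(), seed=3, ligand="L", pathway="P")
        fit = fit_operational([curve])[0]

        def model_linear(a, ka, tau):
            return 100.0 * tau * a / (a + ka + tau * a)

        popt, _ = curve_fit(model_linear, curve.conc, curve.response,
                            p0=[1e-9, 1.0], maxfev=20000)
        assert -np.log10(popt[0]) == pytest.approx(fit.pKA, abs=1e-6)

    def test_recovery_bias_across_parameter_box(self):
        """Median |bias| < 0.05 for pK_A and log tau over random truths."""
        rng = np.random.default_rng(42)
        lay = PlateLayout()
        b_pka, b_lt = [], []
        for _ in range(100):
            pka, lt = rng.uniform(6.5, 10.5), rng.uniform(-0.8, 1.2)
            truth = GroundTruth(
                operational={("L", "P"): OperationalParams(pKA=pka, log_tau=lt)},
                sd_frac=0.05,
            )
            ests = []
            for _e in range(6):
                c = simulate_crc(truth, lay, int(rng.integers(2 ** 31)),
                                 ligand="L", pathway="P")
                f = fit_operational([c])[0]
                if f.converged and np.isfinite(f.pKA):
                    ests.append((f.pKA, f.log_tau))
            ests = np.asarray(ests)
            b_pka.append(ests[:, 0].mean() - pka)
            b_lt.append(ests[:, 1].mean() - lt)
        assert np.median(np.abs(b_pka)) < 0.05
        assert np.median(np.abs(b_lt)) < 0.05

    def test_shared_em_requires_two_curves(self):
        truth = GroundTruth(
            operational={("L", "P"): OperationalParams(pKA=9.0, log_tau=0.3)},
            sd_frac=0.0,
        )
        curve = simulate_crc(truth, PlateLayout(), seed=1, ligand="L", pathway="P")
        with pytest.raises(ValueError):
            fit_operational([curve], em_policy="shared")

    def test_shared_em_joint_fit_flags_weak_identifiability(self):
        truth = GroundTruth(
            operational={
                ("A", "P"): OperationalParams(pKA=9.5, log_tau=0.2),
                ("B", "P"): OperationalParams(pKA=8.0, log_tau=0.6),
            },
            sd_frac=0.02,
        )
        lay = PlateLayout()
        curves = [simulate_crc(truth, lay, s, ligand=l, pathway="P")
                  for s, l in ((1, "A"), (2, "B"))]
        fits = fit_operational(curves, em_policy="shared")
        assert len(fits) == 2
        # with slope 1 the shared Em is only weakly identified
        assert all(f.converged for f in fits)


class TestExpressionAndTau:
    def test_normalize_expression_anchors(self):
        rec = ExpressionRecord(MFI_parental=100.0, MFI_WT=1100.0, MFI_sample=1100.0)
        assert normalize_expression(rec) == pytest.approx(100.0)
        rec = ExpressionRecord(MFI_parental=100.0, MFI_WT=1100.0, MFI_sample=100.0)
        assert normalize_expression(rec) == pytest.approx(0.0)

    def test_normalize_expression_overexpression(self):
        rec = ExpressionRecord(MFI_parental=100.0, MFI_WT=1100.0,
                               MFI_sample=100.0 + 3.2 * 1000.0)
        assert normalize_expression(rec) == pytest.approx(320.0)

    def test_degenerate_anchors_rejected(self):
        rec = ExpressionRecord(MFI_parental=5.0, MFI_WT=5.0, MFI_sample=7.0)
        with pytest.raises(ValueError):
            normalize_expression(rec)

    @pytest.mark.parametrize("log_tau,expr,expected", [
        (0.25, 100.0, 0.25),
        (0.38, 320.0, 0.38 - np.log10(3.2)),
        (-0.11, 11.0, -0.11 - np.log10(0.11)),
    ])
    def test_correct_tau_arithmetic(self, log_tau, expr, expected):
        assert correct_tau(log_tau, expr) == pytest.approx(expected, abs=1e-9)

    def test_correct_tau_undetectable_expression_is_nd(self):
        assert np.isnan(correct_tau(0.3, 0.0))
        assert np.isnan(correct_tau(0.3, np.nan))

    def test_tau_c_preserves_ordering_and_shift(self):
        taus = np.array([-0.5, 0.0, 0.7])
        corrected = np.array([correct_tau(t, 250.0) for t in taus])
        np.testing.assert_allclose(corrected, taus - np.log10(2.5), atol=1e-12)
        assert np.all(np.diff(corrected) > 0)


class TestDeltaAndCorrelation:
    def test_delta_convention(self):
        assert delta_vs_wt(9.54, 8.05) == pytest.approx(1.49)
        assert delta_vs_wt(9.54, 9.54) == 0.0
        assert np.isnan(delta_vs_wt(np.nan, 8.0))

    def test_correlation_limits_and_formula(self):
        x = np.arange(10.0)
        r, p, slope = correlate_affinities(x, x)
        assert r == pytest.approx(1.0) and slope == pytest.approx(1.0)
        r, _, _ = correlate_affinities(x, -x)
        assert r == pytest.approx(-1.0)
        rng = np.random.default_rng(8)
        y = 0.6 * x + rng.normal(0, 1, 10)
        r, _, _ = correlate_affinities(x, y)
        r_direct = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert r == pytest.approx(r_direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_affinities(np.ones(5), np.arange(5.0))
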