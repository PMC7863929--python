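"""Weighted robust quartic fitting: weight function, IRLS, derivatives, mse."""

import numpy as np
import pytest

from hscurve import FitOptions, PrunedCurve, eval_fit, fit_quartic, mse, weight
from hscurve.exceptions import IdentifiabilityError


def _quartic_curve(coeffs, x, noise=None):
    y = np.polyval(coeffs, x)
    if noise is not None:
        y = y + noise
    return PrunedCurve(x=x, y=np.clip(y, 0.0, None))


class TestWeight:
    def test_printed_closed_form(self):
        assert weight(0.0) == pytest.approx(1 / 0.011**2)  # ~8264.4628
        assert weight(1.0) == pytest.approx(1 / 0.022**2)  # ~2066.1157

    def test_strictly_decreasing(self, rng):
        y = np.sort(rng.uniform(0, 2, 50))
        w = weight(y)
        assert np.all(np.diff(w) < 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            weight(-0.1)


class TestFitQuartic:
    def test_noiseless_exact_recovery(self):
        x = np.linspace(0, 1, 20)
        true = np.array([2.0, 0.0, -1.0, 0.0, 0.6])  # y = 2x^4 - x^2 + 0.6 >= 0 on [0,1]
        fit = fit_quartic(_quartic_curve(true, x))
        np.testing.assert_allclose(fit.coeffs, true, atol=1e-6)
        assert fit.mse < 1e-12
        assert fit.converged

    def test_robust_beats_plain_with_gross_outlier(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 1, 30)
        true = np.array([0.5, -0.2, 0.1, 0.05, 0.1])
        y = np.polyval(true, x) + 0.002 * rng.standard_normal(30)
        y[7] += 0.5  # gross outlier
        curve = PrunedCurve(x=x, y=np.clip(y, 0, None))
        robust = fit_quartic(curve, FitOptions(robust=True))
        plain = fit_quartic(curve, FitOptions(robust=False))
        err_r = np.linalg.norm(np.array(robust.coeffs) - true)
        err_p = np.linalg.norm(np.array(plain.coeffs) - true)
        assert err_r < err_p

    def test_matches_weighted_normal_equations_without_robustness(self, rng):
        """Single closed-form weighted solve is the oracle for robust=False."""
        for _ in range(10):
            x = np.sort(rng.uniform(0, 1, 60))
            y = rng.uniform(0, 0.4, 60)
            fit = fit_quartic(PrunedCurve(x=x, y=y), FitOptions(robust=False))
            V = np.vander(x, 5)
            w = weight(y)
            b = np.linalg.solve(V.T @ (w[:, None] * V), V.T @ (w * y))
            np.testing.assert_allclose(fit.coeffs, b, atol=1e-8)

    def test_gradient_stationary_at_convergence(self, rng):
        """At the IRLS fixed point the weighted-objective gradient vanishes."""
        x = np.sort(rng.uniform(0, 1, 125))
        y = np.clip(0.3 * x**2 + 0.05 + 0.01 * rng.standard_normal(125), 0, None)
        fit = fit_quartic(PrunedCurve(x=x, y=y), FitOptions())
        assert fit.converged
        V = np.vander(x, 5)
        resid = y - V @ np.array(fit.coeffs)
        w = weight(y)
        s = np.median(np.abs(np.sqrt(w) * resid)) / 0.6745
        u = np.sqrt(w) * resid / (4.685 * s)
        r = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        grad = V.T @ (w * r * resid)  # -0.5 * d(objective)/db
        assert np.max(np.abs(grad)) < 1e-6 * (1 + np.sum(w))

    def test_constant_response_fits_constant_polynomial(self):
        fit = fit_quartic(PrunedCurve(x=np.linspace(0, 1, 10), y=np.full(10, 0.07)))
        assert fit.coeffs[:4] == (0.0, 0.0, 0.0, 0.0)
        assert fit.coeffs[4] == pytest.approx(0.07)
        assert fit.mse == 0.0

    def test_too_few_distinct_x(self):
        with pytest.raises(IdentifiabilityError):
            fit_quartic(PrunedCurve(x=np.array([0.0, 0.1, 0.2, 0.3]), y=np.zeros(4)))

    def test_coefficient_error_shrinks_with_noise(self):
        """Median coefficient L2 error decreases as the noise level drops."""
        x = np.linspace(-1, 1, 125)

        def median_err(sigma, n_rep=30):
            errs = []
            for s in range(n_rep):
                r = np.random.default_rng(s)
                b = r.uniform(-1, 1, 5)
                b[4] += 0.05 - np.polyval(b, x).min()
                y = np.clip(np.polyval(b, x) + sigma * r.standard_normal(125), 0, None)
                fit = fit_quartic(PrunedCurve(x=x, y=y))
                errs.append(np.linalg.norm(np.array(fit.coeffs) - b))
            return np.median(errs)

        assert median_err(0.001) < median_err(0.01) < median_err(0.05)

    def test_quintic_does_not_beat_quartic_on_quartic_truth(self):
        """A degree-5 fit on quartic truth only chases noise (overfitting guard)."""
        rng = np.random.default_rng(11)
        x = np.linspace(0, 1, 125)
        true = np.array([0.4, -0.3, 0.2, 0.05, 0.1])
        y_true = np.polyval(true, x)
        grid = np.linspace(0, 1, 500)
        f_true = np.polyval(true, grid)
        gaps = []
        for _ in range(20):
            y = y_true + 0.01 * rng.standard_normal(125)
            e4 = np.mean((np.polyval(np.polyfit(x, y, 4), grid) - f_true) ** 2)
            e5 = np.mean((np.polyval(np.polyfit(x, y, 5), grid) - f_true) ** 2)
            gaps.append(e4 - e5)
        # on average the extra degree does not reduce true error beyond the noise floor
        assert np.mean(gaps) < 1e-5


class TestEvalFit:
    def _fit(self, coeffs):
        return fit_quartic(
            PrunedCurve(x=np.linspace(0, 1, 9), y=np.clip(np.polyval(coeffs, np.linspace(0, 1, 9)), 0, None))
        )

    def test_linear_case(self):
        f, df, ddf = eval_fit(self._fit([0, 0, 0, 1, 0]), np.array([0.3, 0.9]))
        np.testing.assert_allclose(df, 1.0, atol=1e-8)
        np.testing.assert_allclose(ddf, 0.0, atol=1e-7)

    def test_pure_quartic_monomial(self):
        fit = self._fit([1, 0, 0, 0, 0])
        f, df, ddf = eval_fit(fit, 1.0)
        assert f == pytest.approx(1.0, abs=1e-8)
        assert df == pytest.approx(4.0, abs=1e-7)
        assert ddf == pytest.approx(12.0, abs=1e-6)

    def test_derivatives_match_finite_differences(self, rng):
        for _ in range(10):
            coeffs = tuple(rng.uniform(-1, 1, 5))
            from hscurve import QuarticFit

            fit = QuarticFit(coeffs=coeffs, x_range=(0, 1), converged=True,
                             n_iter=1, objective=0.0, mse=0.0, n_points=9)
            x = rng.uniform(0.1, 0.9, 5)
            h = 1e-5
            f, df, ddf = eval_fit(fit, x)
            fp = (fit(x + h) - fit(x - h)) / (2 * h)
            fpp = (fit(x + h) - 2 * fit(x) + fit(x - h)) / h**2
            np.testing.assert_allclose(df, fp, atol=1e-6)
            np.testing.assert_allclose(ddf, fpp, atol=1e-4)


class TestMse:
    def test_perfect_fit_zero(self):
        x = np.linspace(0, 1, 12)
        curve = _quartic_curve([0.2, 0, 0, 0, 0.1], x)
        fit = fit_quartic(curve)
        assert mse(fit, curve) < 1e-15

    def test_hand_residuals(self):
        from hscurve import QuarticFit

        fit = QuarticFit(coeffs=(0, 0, 0, 0, 0.2), x_range=(0, 1), converged=True,
                         n_iter=0, objective=0.0, mse=0.0, n_points=2)
        curve = PrunedCurve(x=np.array([0.2, 0.8]), y=np.array([0.3, 0.1]))
        assert mse(fit, curve) == pytest.approx(0.01)  # residuals (0.1, -0.1)

    def test_matches_direct_summation(self, rng):
        for _ in range(10):
            x = np.sort(rng.uniform(0, 1, 40))
            y = rng.uniform(0, 0.4, 40)
            curve = PrunedCurve(x=x, y=y)
            fit = fit_quartic(curve)
            direct = sum((y[i] - np.polyval(fit.coeffs, x[i])) ** 2 for i in range(40)) / 40
            assert mse(fit, curve) == pytest.approx(direct, abs=1e-12)
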