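"""Derivative features of fitted curves and per-cube extremum summaries."""

import numpy as np
import pytest

from hscurve import (
    CurveFeatures,
    PrunedCurve,
    QuarticFit,
    ROIWindow,
    compute_features,
    fit_quartic,
    summarize_cube,
)


def _fit(coeffs):
    return QuarticFit(coeffs=tuple(float(c) for c in coeffs), x_range=(0.0, 1.0),
                      converged=True, n_iter=1, objective=0.0, mse=0.0, n_points=10)


def _curve(x, y=None):
    x = np.asarray(x, dtype=float)
    return PrunedCurve(x=x, y=np.zeros_like(x) if y is None else np.asarray(y, float))


def _feat(totm=0.0, mean=0.0, prod=0.0, mabdf=0.0, window=(0, 0)):
    return CurveFeatures(df_mean=0, ddf_mean=0, df_at_max=0, totm=totm, mean=mean,
                         abs_df_mean=0, mabdf=mabdf, prod=prod, inflections=0,
                         window=ROIWindow(center=window))


class TestComputeFeatures:
    def test_linear_fit(self):
        """f = x on [0,1]: df=1 everywhere, totm = 1*1 + 0.1*0 + 1 = 2."""
        f = compute_features(_fit([0, 0, 0, 1, 0]), _curve(np.linspace(0, 1, 11)))
        assert f.df_mean == pytest.approx(1.0)
        assert f.ddf_mean == pytest.approx(0.0)
        assert f.df_at_max == pytest.approx(1.0)
        assert f.totm == pytest.approx(2.0)

    def test_figure_variant_drops_df_at_max(self):
        f = compute_features(_fit([0, 0, 0, 1, 0]), _curve(np.linspace(0, 1, 11)),
                             totm_variant="figure")
        assert f.totm == pytest.approx(1.0)

    def test_flat_fit(self):
        x = np.linspace(0.2, 0.6, 9)
        f = compute_features(_fit([0, 0, 0, 0, 0.04]), _curve(x))
        assert f.mean == pytest.approx(0.04)
        assert f.abs_df_mean == pytest.approx(0.0)
        assert f.mabdf == pytest.approx(0.04)
        assert f.prod == pytest.approx(0.04 * 0.6)

    def test_matches_bruteforce_enumeration(self, rng):
        """Every feature equals direct summation over explicitly listed points."""
        for _ in range(10):
            c = rng.uniform(-1, 1, 5)
            x = np.sort(rng.uniform(0.1, 0.9, 17))
            feats = compute_features(_fit(c), _curve(x))
            fv = np.array([sum(c[4 - k] * xi**k for k in range(5)) for xi in x])
            dv = np.array([sum(k * c[4 - k] * xi ** (k - 1) for k in range(1, 5)) for xi in x])
            sv = np.array([sum(k * (k - 1) * c[4 - k] * xi ** (k - 2) for k in range(2, 5)) for xi in x])
            i_max = int(np.argmax(fv))
            assert feats.df_mean == pytest.approx(dv.mean(), abs=1e-10)
            assert feats.ddf_mean == pytest.approx(sv.mean(), abs=1e-10)
            assert feats.df_at_max == pytest.approx(dv[i_max], abs=1e-10)
            assert feats.totm == pytest.approx(dv.mean() + 0.1 * sv.mean() + dv[i_max], abs=1e-10)
            assert feats.mean == pytest.approx(fv.mean(), abs=1e-10)
            assert feats.mabdf == pytest.approx(fv.mean() + np.abs(dv).mean(), abs=1e-10)
            assert feats.prod == pytest.approx(x.max() * fv.max(), abs=1e-10)

    def test_vertical_shift_law(self):
        """+delta on the fitted values shifts mean/mabdf by +delta, derivatives unchanged."""
        c = [0.3, -0.2, 0.1, 0.05, 0.1]
        x = np.linspace(0.1, 0.8, 15)
        base = compute_features(_fit(c), _curve(x))
        shifted = compute_features(_fit(c[:4] + [c[4] + 0.25]), _curve(x))
        assert shifted.mean == pytest.approx(base.mean + 0.25, abs=1e-12)
        assert shifted.mabdf == pytest.approx(base.mabdf + 0.25, abs=1e-12)
        assert shifted.df_mean == pytest.approx(base.df_mean, abs=1e-12)
        assert shifted.ddf_mean == pytest.approx(base.ddf_mean, abs=1e-12)
        assert shifted.totm == pytest.approx(base.totm, abs=1e-12)

    def test_x_scaling_chain_rule(self):
        """Scaling x by s (with refit) scales df by 1/s and ddf by 1/s^2."""
        true = np.array([0.5, -0.1, 0.2, 0.1, 0.2])
        x = np.linspace(0.1, 1.0, 40)
        y = np.polyval(true, x)
        s = 2.5
        base = compute_features(fit_quartic(_curve(x, y)), _curve(x, y))
        scaled_curve = _curve(s * x, y)
        scaled = compute_features(fit_quartic(scaled_curve), scaled_curve)
        assert scaled.df_mean == pytest.approx(base.df_mean / s, rel=1e-6)
        assert scaled.ddf_mean == pytest.approx(base.ddf_mean / s**2, rel=1e-6)
        assert scaled.mean == pytest.approx(base.mean, rel=1e-6)

    @pytest.mark.parametrize("coeffs,expected", [
        ([0, 0, 1, 0, 0], 0),            # f'' = 2 > 0, no sign change
        ([0, 1, -1.5, 0, 0], 1),         # f'' = 6x - 3, root at 0.5
        ([1, -2, 0.9, 0, 0], 2),         # f'' = 12x^2 - 12x + 1.8, two roots in (0,1)
    ])
    def test_inflection_count(self, coeffs, expected):
        f = compute_features(_fit(coeffs), _curve(np.linspace(0, 1, 21)))
        assert f.inflections == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            _curve(np.array([]))


class TestSummarize:
    def test_single_curve_is_its_own_extrema(self):
        f = _feat(totm=1.5, mean=0.2, prod=0.1, mabdf=0.3)
        s = summarize_cube([f])
        assert (s.max_totm, s.max_mean, s.max_prod) == (1.5, 0.2, 0.1)
        assert (s.min_mean, s.min_mabdf) == (0.2, 0.3)
        assert s.n_curves == 1

    def test_max_totm_picks_larger(self):
        s = summarize_cube([_feat(totm=2.0), _feat(totm=5.0123, window=(3, 4))])
        assert s.max_totm == 5.0123
        assert s.arg_windows["max_totm"] == (3, 4)

    def test_matches_bruteforce_scan(self, rng):
        feats = [_feat(totm=rng.uniform(-1, 5), mean=rng.uniform(0, 0.4),
                       prod=rng.uniform(0, 1), mabdf=rng.uniform(0, 0.5),
                       window=(int(rng.integers(0, 50)), int(rng.integers(0, 50))))
                 for _ in range(60)]
        s = summarize_cube(feats)
        assert s.max_totm == max(f.totm for f in feats)
        assert s.max_mean == max(f.mean for f in feats)
        assert s.max_prod == max(f.prod for f in feats)
        assert s.min_mean == min(f.mean for f in feats)
        assert s.min_mabdf == min(f.mabdf for f in feats)

    def test_permutation_invariant(self, rng):
        feats = [_feat(totm=t, mean=m, window=(i, i))
                 for i, (t, m) in enumerate(zip(rng.uniform(0, 3, 20), rng.uniform(0, 0.3, 20)))]
        a = summarize_cube(feats)
        b = summarize_cube(list(reversed(feats)))
        assert a == b

    def test_tie_breaks_to_lowest_window(self):
        s = summarize_cube([_feat(totm=2.0, window=(9, 1)), _feat(totm=2.0, window=(2, 8)),
                            _feat(totm=2.0, window=(2, 3))])
        assert s.arg_windows["max_totm"] == (2, 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_cube([])
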