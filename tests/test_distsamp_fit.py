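"""Detection-function likelihood fitting, model selection and goodness of fit."""

from types import SimpleNamespace

import numpy as np
import pytest
from scipy import integrate

from settdens.distsamp import (
    DetectionFunction,
    fit_detection,
    select_model,
    simulate_distances,
    truncate,
)


class TestTruncate:
    def test_fixed_w_keeps_everything_within(self):
        d = np.linspace(0, 54, 30)
        ds = truncate(d, mode="fixed_w", value=55.0)
        assert ds.n == 30 and ds.removed_fraction == 0.0 and ds.w == 55.0

    def test_percent_matches_order_statistics(self, rng):
        d = rng.uniform(0, 100, size=1000)
        ds = truncate(d, mode="percent", value=0.10)
        assert ds.n == 900
        srt = np.sort(d)
        assert ds.w == pytest.approx(srt[899])          # max retained
        assert ds.w == pytest.approx(np.quantile(d, 0.9), abs=1.0)
        assert ds.removed_fraction == pytest.approx(0.10)

    def test_fixed_w_drops_the_far_tail(self):
        d = np.array([10.0, 54.0, 55.0, 56.0, 80.0])
        ds = truncate(d, mode="fixed_w", value=55.0)
        assert ds.n == 3  # strictly beyond 55 m removed

    @pytest.mark.parametrize("mode,value", [("fixed_w", -1), ("percent", 1.0)])
    def test_bad_values_rejected(self, mode, value):
        with pytest.raises(ValueError):
            truncate(np.array([1.0, 2.0]), mode=mode, value=value)


class TestLikelihood:
    def test_loglike_matches_hand_quadrature(self):
        # half-normal sigma=15, w=55, x = {5, 10, 20}
        x = np.array([5.0, 10.0, 20.0])
        model = DetectionFunction(x, w=55.0, key="half_normal")
        sigma = 15.0

        def g(u):
            return np.exp(-(u**2) / (2 * sigma**2))

        mu, _ = integrate.quad(g, 0, 55)
        expected = float(np.sum(np.log(g(x))) - 3 * np.log(mu))
        assert model.loglike(np.array([np.log(sigma)])) == pytest.approx(expected, abs=1e-8)

    def test_half_normal_parameter_recovery_within_3se(self):
        x = simulate_distances(2000, "half_normal", 55.0, sigma=15.0, rng=7)
        res = fit_detection(x, w=55.0, key="half_normal")
        se = res.bse()["sigma"]
        assert abs(res.sigma() - 15.0) <= 3 * se

    def test_aic_identity(self):
        x = simulate_distances(300, "hazard_rate", 55.0, sigma=15.0, b=2.5, rng=11)
        for key in ("uniform", "half_normal", "hazard_rate"):
            res = fit_detection(x, w=55.0, key=key)
            assert res.aic == pytest.approx(-2 * res.llf + 2 * res.n_params, abs=1e-9)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            fit_detection(np.array([5.0, 6.0, 7.0]), w=55.0, key="half_normal")

    def test_adjustments_added_only_while_aic_improves(self):
        # strongly non-half-normal shape: uniform key needs cosine terms
        x = simulate_distances(800, "hazard_rate", 55.0, sigma=12.0, b=3.0, rng=5)
        plain = fit_detection(x, w=55.0, key="uniform")
        adj = fit_detection(x, w=55.0, key="uniform", adjustment="cosine")
        assert adj.aic < plain.aic
        assert adj.is_monotone()


class TestStratification:
    def test_cds_equals_independent_fits(self):
        import pandas as pd

        xa = simulate_distances(300, "half_normal", 55.0, sigma=20.0, rng=1)
        xb = simulate_distances(300, "half_normal", 55.0, sigma=10.0, rng=2)
        obs = pd.DataFrame({
            "distance_m": np.concatenate([xa, xb]),
            "site_habitat": ["forested"] * 300 + ["hedgerow"] * 300,
        })
        strat = fit_detection(obs, w=55.0, key="half_normal", stratify_by="site_habitat")
        fa = fit_detection(xa, w=55.0, key="half_normal")
        fb = fit_detection(xb, w=55.0, key="half_normal")
        assert strat.llf == pytest.approx(fa.llf + fb.llf, abs=1e-6)
        assert strat.aic == pytest.approx(fa.aic + fb.aic, abs=1e-6)
        assert strat.esw("forested") == pytest.approx(fa.esw(), abs=1e-6)

    def test_mcds_scale_covariate_recovers_level_scales(self):
        import pandas as pd

        xa = simulate_distances(700, "half_normal", 55.0, sigma=20.0, rng=3)
        xb = simulate_distances(700, "half_normal", 55.0, sigma=10.0, rng=4)
        obs = pd.DataFrame({
            "distance_m": np.concatenate([xa, xb]),
            "site_habitat": ["forested"] * 700 + ["hedgerow"] * 700,
        })
        res = fit_detection(obs, w=55.0, key="half_normal", scale_covariate="site_habitat")
        assert res.sigma("forested") == pytest.approx(20.0, rel=0.15)
        assert res.sigma("hedgerow") == pytest.approx(10.0, rel=0.15)
        assert res.n_params == 2


class TestSelection:
    def _fake(self, aic, n_params, key, x=(1.0, 2.0), w=55.0):
        return SimpleNamespace(aic=aic, n_params=n_params, key=key, w=w,
                               model=SimpleNamespace(x=np.asarray(x)))

    def test_single_candidate(self):
        m = self._fake(100.0, 2, "hazard_rate")
        assert select_model([m]) is m

    def test_lowest_aic_wins(self):
        a = self._fake(856.66, 4, "hazard_rate")
        b = self._fake(875.30, 2, "hazard_rate")
        assert select_model([a, b]) is a

    def test_tie_broken_by_fewer_parameters(self):
        a = self._fake(100.0, 3, "hazard_rate")
        b = self._fake(100.0, 4, "hazard_rate")
        assert select_model([a, b]) is a

    def test_tie_broken_by_key_order(self):
        a = self._fake(100.0, 2, "hazard_rate")
        b = self._fake(100.0, 2, "half_normal")
        assert select_model([a, b]) is b

    def test_half_normal_data_mostly_selects_half_normal(self):
        hits = 0
        for seed in range(20):
            x = simulate_distances(500, "half_normal", 55.0, sigma=15.0,
                                   rng=500 + seed)
            hn = fit_detection(x, w=55.0, key="half_normal")
            hr = fit_detection(x, w=55.0, key="hazard_rate")
            hits += select_model([hn, hr]).key == "half_normal"
        assert hits > 10  # AIC should not systematically prefer the extra parameter

    def test_different_data_rejected(self):
        a = self._fake(100.0, 2, "hazard_rate", x=(1.0, 2.0))
        b = self._fake(100.0, 2, "hazard_rate", x=(1.0, 3.0))
        with pytest.raises(ValueError, match="different data"):
            select_model([a, b])


class TestGoodnessOfFit:
    def test_two_bin_hand_arithmetic(self):
        # uniform key, equal bins: expected {50, 50}; observed {60, 40} -> chi2 = 4
        x = np.concatenate([np.full(60, 10.0), np.full(40, 40.0)])
        res = fit_detection(x, w=50.0, key="uniform")
        chi2, df, p = res.gof_chi2(n_bins=2)
        assert chi2 == pytest.approx(4.0, abs=1e-9)
        assert df == 1

    def test_perfect_fit_gives_zero(self):
        x = np.concatenate([np.full(50, 10.0), np.full(50, 40.0)])
        res = fit_detection(x, w=50.0, key="uniform")
        chi2, df, p = res.gof_chi2(n_bins=2)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_df_formula_one_param_key(self):
        x = simulate_distances(600, "half_normal", 55.0, sigma=15.0, rng=9)
        res = fit_detection(x, w=55.0, key="half_normal")
        _, df, _ = res.gof_chi2(n_bins=6)
        assert df == 4  # 6 bins - 1 parameter - 1

    def test_sparse_bins_merged_with_warning(self):
        x = simulate_distances(30, "half_normal", 55.0, sigma=6.0, rng=10)
        res = fit_detection(x, w=55.0, key="half_normal")
        with pytest.warns(UserWarning, match="merging"):
            chi2, df, _ = res.gof_chi2(n_bins=8)
        assert df >= 1
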