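"""The MR estimator panel against hand computations and independent oracles."""

import numpy as np
import pytest
from scipy import stats

from mrmediate.estimators import (
    EggerEstimator,
    IVWEstimator,
    ModeEstimator,
    WeightedMedianEstimator,
    beta_to_or,
    cochran_q,
    ivw_mre,
    run_method_panel,
    wald_ratio,
)

from conftest import make_harmonized


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,sx,by,sy,beta,se",
        [
            (0.10, 0.01, 0.02, 0.01, 0.2, 0.1),
            (0.10, 0.01, 0.0, 0.01, 0.0, 0.1),
            (-0.10, 0.01, 0.02, 0.01, -0.2, 0.1),
        ],
    )
    def test_direct_division(self, bx, sx, by, sy, beta, se):
        got_beta, got_se = wald_ratio(bx, sx, by, sy)
        assert got_beta == pytest.approx(beta)
        assert got_se == pytest.approx(se)

    def test_zero_exposure_beta_fatal(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.02, 0.01)


class TestIVW:
    def test_two_instrument_hand_computation(self):
        h = make_harmonized([1, 1], 0.05, [0.5, 0.3], 0.1)
        res, het = ivw_mre(h)
        assert res.beta == pytest.approx(0.4)
        assert het.q == pytest.approx(2.0)
        assert het.df == 1
        est = IVWEstimator().fit(h)
        assert est.fixed_se_ == pytest.approx(1 / np.sqrt(200), rel=1e-12)  # ~0.0707
        assert est.se_ == pytest.approx(0.1, rel=1e-12)  # MRE inflation sqrt(Q/1)

    def test_identical_ratios_degenerate(self):
        h = make_harmonized([1, 2, 4], 0.01, [0.3, 0.6, 1.2], 0.1)
        est = IVWEstimator().fit(h)
        assert est.estimate_ == pytest.approx(0.3)
        assert est.q_ == pytest.approx(0.0, abs=1e-20)
        assert est.se_ == est.fixed_se_
        assert est.q_pvalue_ == pytest.approx(1.0)

    def test_single_instrument_reduces_to_wald_ratio(self):
        h = make_harmonized([0.1], [0.01], [0.02], [0.01])
        est = IVWEstimator().fit(h)
        beta, se = wald_ratio(0.1, 0.01, 0.02, 0.01)
        assert est.estimate_ == pytest.approx(beta)
        assert est.se_ == pytest.approx(se)

    def test_matches_statsmodels_wls_oracle(self, random_instruments):
        import statsmodels.api as sm

        est = IVWEstimator().fit(random_instruments)
        w = 1.0 / random_instruments.se_outcome**2
        fit = sm.WLS(
            random_instruments.beta_outcome,
            random_instruments.beta_exposure[:, None],
            weights=w,
        ).fit()
        assert est.estimate_ == pytest.approx(fit.params[0], abs=1e-10)
        # fixed-effects SE is the WLS SE with the residual variance set to 1
        assert est.fixed_se_ == pytest.approx(np.sqrt(fit.cov_params()[0, 0] / fit.scale), abs=1e-10)
        # and Cochran's Q is the weighted residual sum of squares
        assert est.q_ == pytest.approx(float(np.sum(w * fit.resid**2)), abs=1e-8)

    def test_mre_se_never_below_fixed(self, random_instruments):
        est = IVWEstimator().fit(random_instruments)
        assert est.se_ >= est.fixed_se_


class TestEgger:
    def test_exact_proportional_fit(self):
        h = make_harmonized([1, 2, 3], 0.01, [0.5, 1.0, 1.5], 0.1)
        est = EggerEstimator().fit(h)
        assert est.estimate_ == pytest.approx(0.5, abs=1e-12)
        assert est.intercept_ == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit_recovers_intercept(self):
        bx = np.array([1.0, 2.0, 3.0, 4.0])
        by = 0.1 + 0.3 * bx
        h = make_harmonized(bx, 0.01, by, 0.1)
        est = EggerEstimator().fit(h)
        assert est.intercept_ == pytest.approx(0.1, abs=1e-12)
        assert est.estimate_ == pytest.approx(0.3, abs=1e-12)

    def test_matches_statsmodels_wls_oracle(self, random_instruments):
        import statsmodels.api as sm

        est = EggerEstimator().fit(random_instruments)
        bx = random_instruments.beta_exposure
        by = random_instruments.beta_outcome
        flip = np.sign(bx)
        bx, by = bx * flip, by * flip
        w = 1.0 / random_instruments.se_outcome**2
        fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        assert est.estimate_ == pytest.approx(fit.params[1], abs=1e-10)
        assert est.intercept_ == pytest.approx(fit.params[0], abs=1e-10)
        # fixture is over-dispersed, so the multiplicative floor is inactive
        # and SEs/t p-values coincide with the WLS ones
        assert est.residual_scale_ > 1
        assert est.se_ == pytest.approx(fit.bse[1], abs=1e-10)
        assert est.intercept_se_ == pytest.approx(fit.bse[0], abs=1e-10)
        assert est.pvalue_ == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_requires_three_instruments(self):
        h = make_harmonized([1, 2], 0.01, [0.5, 1.0], 0.1)
        with pytest.raises(ValueError, match="at least 3"):
            EggerEstimator().fit(h)

    def test_orientation_invariance(self, random_instruments):
        """Flipping the allele coding of any instrument leaves the fit
        unchanged (canonical orientation)."""
        est1 = EggerEstimator().fit(random_instruments)
        table = random_instruments.table.copy()
        table.loc[3, ["beta_exposure", "beta_outcome"]] *= -1
        from mrmediate.sumstats import HarmonizedInstrumentSet

        flipped = HarmonizedInstrumentSet("e", "o", table)
        est2 = EggerEstimator().fit(flipped)
        assert est1.estimate_ == pytest.approx(est2.estimate_, rel=1e-12)
        assert est1.intercept_ == pytest.approx(est2.intercept_, rel=1e-12)


class TestWeightedMedian:
    def test_equal_weights_lands_on_middle_ratio(self):
        h = make_harmonized([1, 1, 1], 0.01, [0.1, 0.2, 0.3], 0.1)
        est = WeightedMedianEstimator(n_boot=100, random_state=1).fit(h)
        assert est.estimate_ == pytest.approx(0.2)

    def test_hand_interpolation_oracle(self):
        rng = np.random.default_rng(2)
        n = 11
        bx = rng.uniform(0.05, 0.2, n)
        by = rng.normal(0.3, 0.1, n) * bx
        sy = rng.uniform(0.005, 0.02, n)
        h = make_harmonized(bx, 0.004, by, sy)
        est = WeightedMedianEstimator(n_boot=10, random_state=1).fit(h)

        ratios = by / bx
        weights = (bx / sy) ** 2
        order = np.argsort(ratios)
        r, w = ratios[order], weights[order]
        s = (np.cumsum(w) - w / 2) / w.sum()
        k = np.searchsorted(s, 0.5)
        expected = r[k - 1] + (r[k] - r[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1])
        assert est.estimate_ == pytest.approx(expected, rel=1e-12)

    def test_identical_ratios_give_tiny_bootstrap_se(self):
        h = make_harmonized([1, 1, 1, 1], 1e-6, [0.25, 0.25, 0.25, 0.25], 1e-6)
        est = WeightedMedianEstimator(n_boot=200, random_state=3).fit(h)
        assert est.estimate_ == pytest.approx(0.25)
        assert est.se_ < 1e-5

    def test_concentrated_weight_dominates(self):
        # weight ~ (bx/sy)^2: one instrument carries ~99.9% of the weight
        bx = np.array([1.0, 0.01, 0.01])
        by = np.array([0.7, 0.001, 0.003])
        h = make_harmonized(bx, 0.001, by, 0.01)
        est = WeightedMedianEstimator(n_boot=10, random_state=1).fit(h)
        assert est.estimate_ == pytest.approx(0.7, abs=1e-3)

    def test_estimate_within_ratio_range(self, random_instruments):
        est = WeightedMedianEstimator(n_boot=50, random_state=1).fit(random_instruments)
        ratios = random_instruments.beta_outcome / random_instruments.beta_exposure
        assert ratios.min() <= est.estimate_ <= ratios.max()


class TestMode:
    @staticmethod
    def _grid_oracle(ratios, weights, h):
        grid = np.linspace(ratios.min() - h, ratios.max() + h, 20001)
        dens = np.zeros_like(grid)
        for r, w in zip(ratios, weights):
            dens += w * stats.norm.pdf(grid, loc=r, scale=h)
        return grid[np.argmax(dens)]

    def test_majority_cluster_wins_unweighted(self):
        h = make_harmonized([1, 1, 1, 1], 0.01, [0.2, 0.2, 0.2, 0.9], 0.05)
        est = ModeEstimator(weighted=False, n_boot=10, random_state=1).fit(h)
        assert abs(est.estimate_ - 0.2) < est.bandwidth_
        oracle = self._grid_oracle(np.array([0.2, 0.2, 0.2, 0.9]), np.ones(4), est.bandwidth_)
        assert est.estimate_ == pytest.approx(oracle, abs=2 * est.bandwidth_ / 512)

    def test_all_ratios_equal(self):
        h = make_harmonized([1, 2, 3], 0.01, [0.4, 0.8, 1.2], 0.05)
        est = ModeEstimator(n_boot=10, random_state=1).fit(h)
        assert est.estimate_ == pytest.approx(0.4)

    def test_weighted_mode_follows_weight(self):
        # two clusters; precision (weight) heavily favours the 0.8 cluster
        bx = np.array([1.0, 1.0, 0.05, 0.05, 0.05])
        ratios = np.array([0.8, 0.82, 0.2, 0.21, 0.19])
        by = ratios * bx
        h = make_harmonized(bx, 0.001, by, 0.02)
        simple = ModeEstimator(weighted=False, n_boot=10, random_state=1).fit(h)
        weighted = ModeEstimator(weighted=True, n_boot=10, random_state=1).fit(h)
        assert abs(simple.estimate_ - 0.2) < 0.1   # majority cluster
        assert abs(weighted.estimate_ - 0.8) < 0.1  # high-precision cluster
        w = (bx / 0.02) ** 2
        oracle = self._grid_oracle(ratios, w, weighted.bandwidth_)
        assert weighted.estimate_ == pytest.approx(oracle, abs=2 * weighted.bandwidth_ / 512)

    def test_random_set_matches_grid_oracle(self, random_instruments):
        est = ModeEstimator(weighted=True, n_boot=10, random_state=1).fit(random_instruments)
        ratios = random_instruments.beta_outcome / random_instruments.beta_exposure
        w = (random_instruments.beta_exposure / random_instruments.se_outcome) ** 2
        oracle = self._grid_oracle(ratios, w, est.bandwidth_)
        assert est.estimate_ == pytest.approx(oracle, abs=est.bandwidth_ / 50)

    def test_mode_within_extended_ratio_range(self, random_instruments):
        est = ModeEstimator(n_boot=10, random_state=1).fit(random_instruments)
        ratios = random_instruments.beta_outcome / random_instruments.beta_exposure
        assert ratios.min() - est.bandwidth_ <= est.estimate_ <= ratios.max() + est.bandwidth_


class TestCochranQ:
    def test_hand_computation(self):
        h = make_harmonized([1, 1], 0.05, [0.5, 0.3], 0.1)
        het = cochran_q(h, 0.4)
        assert het.q == pytest.approx(2.0)
        assert het.df == 1
        assert het.q_pvalue == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_perfect_fit(self):
        h = make_harmonized([1, 2], 0.05, [0.3, 0.6], 0.1)
        het = cochran_q(h, 0.3)
        assert het.q == pytest.approx(0.0, abs=1e-25)
        assert het.q_pvalue == pytest.approx(1.0)

    def test_doubling_outcome_se_quarters_q(self):
        h1 = make_harmonized([1, 1], 0.05, [0.5, 0.3], 0.1)
        h2 = make_harmonized([1, 1], 0.05, [0.5, 0.3], 0.2)
        assert cochran_q(h2, 0.4).q == pytest.approx(cochran_q(h1, 0.4).q / 4)


class TestBetaToOR:
    def test_null_and_symmetry(self):
        assert beta_to_or(0.0, 0.1)[0] == pytest.approx(1.0)
        assert beta_to_or(-np.log(2), 0.1)[0] == pytest.approx(0.5)

    def test_reported_or_and_ci_shape(self):
        # log(1.75) with the SE implied by a (1.59, 1.92) 95% CI
        se = (np.log(1.92) - np.log(1.59)) / (2 * 1.96)
        or_, lo, hi = beta_to_or(np.log(1.75), se)
        assert or_ == pytest.approx(1.75)
        assert lo == pytest.approx(1.59, abs=0.005)
        assert hi == pytest.approx(1.92, abs=0.005)

    def test_scale_guard(self):
        with pytest.raises(ValueError, match="log_odds"):
            beta_to_or(0.1, 0.05, scale="sd")


class TestPanel:
    def test_full_panel_on_three_instruments(self):
        h = make_harmonized([1, 2, 3], 0.01, [0.52, 0.98, 1.55], 0.1)
        report = run_method_panel(h, n_boot=50)
        assert set(report.results) == {"ivw_mre", "egger", "weighted_median", "simple_mode", "weighted_mode"}
        assert report.n_snps == 3
        frame = report.to_frame()
        assert (frame["ci_low"] <= frame["beta"]).all()
        assert (frame["beta"] <= frame["ci_high"]).all()

    def test_single_instrument_degrades_to_wald(self):
        h = make_harmonized([0.1], [0.01], [0.02], [0.01])
        report = run_method_panel(h)
        assert set(report.results) == {"wald_ratio"}
        assert "ivw_mre" in report.absent

    def test_two_instruments_give_ivw_only(self):
        h = make_harmonized([1, 1], 0.05, [0.5, 0.3], 0.1)
        report = run_method_panel(h)
        assert set(report.results) == {"ivw_mre"}
        assert "egger" in report.absent

    @pytest.mark.parametrize("cls,kwargs", [
        (IVWEstimator, {}),
        (EggerEstimator, {}),
        (WeightedMedianEstimator, {"n_boot": 20, "random_state": 5}),
        (ModeEstimator, {"weighted": True, "n_boot": 20, "random_state": 5}),
    ])
    def test_sklearn_protocol(self, cls, kwargs, random_instruments):
        from sklearn.base import clone

        est = cls(**kwargs)
        params = est.get_params()
        cloned = clone(est)
        assert cloned.get_params() == params
        est.fit(random_instruments)
        refit = clone(est).fit(random_instruments)
        assert refit.estimate_ == est.estimate_

    def test_sign_flip_invariance_all_estimators(self, random_instruments):
        """Simultaneously recoding (bx, by) for arbitrary instruments leaves
        every panel estimate unchanged."""
        from mrmediate.sumstats import HarmonizedInstrumentSet

        table = random_instruments.table.copy()
        flip_rows = [0, 2, 5, 11]
        table.loc[flip_rows, ["beta_exposure", "beta_outcome"]] *= -1
        flipped = HarmonizedInstrumentSet("e", "o", table)
        r1 = run_method_panel(random_instruments, n_boot=10)
        r2 = run_method_panel(flipped, n_boot=10)
        for method in r1.results:
            assert r1.results[method].beta == pytest.approx(r2.results[method].beta, rel=1e-9), method
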