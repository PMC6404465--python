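import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_hset, hset_from_ratios
from ivmr.errors import (
    DomainError,
    InsufficientInstrumentsError,
    WeakInstrumentError,
)
from ivmr.estimators import (
    egger,
    i2_gx,
    ivw,
    simex_egger,
    wald_ratios,
    weighted_median,
    weighted_median_point,
)


class TestWaldRatios:
    def test_direct_formula(self, make_hset):
        h = make_hset([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.01, 0.01])
        r = wald_ratios(h)
        assert r.theta[0] == pytest.approx(0.5)
        assert r.se[0] == pytest.approx(0.1)

    def test_null_outcome_gives_zero_ratios(self, make_hset):
        h = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.0] * 3, [0.01] * 3)
        assert wald_ratios(h).theta.tolist() == [0.0, 0.0, 0.0]

    def test_zero_exposure_beta_names_snp(self, make_hset):
        h = make_hset([0.1, 0.0], [0.01, 0.01], [0.05, 0.1], [0.01, 0.01],
                      rsids=["rsA", "rsB"])
        with pytest.raises(WeakInstrumentError, match="rsB"):
            wald_ratios(h)

    def test_second_order_se_against_monte_carlo_oracle(self, make_hset):
        # oracle: empirical SD of the ratio over 1e6 normal draws
        bX, sX, bY, sY = 0.1, 0.01, 0.05, 0.01
        rng = np.random.default_rng(99)
        mc_sd = np.std(rng.normal(bY, sY, 10**6) / rng.normal(bX, sX, 10**6))
        h = make_hset([bX, 0.2], [sX, 0.01], [bY, 0.1], [sY, 0.01])
        r = wald_ratios(h, se_order="second")
        assert r.se[0] == pytest.approx(mc_sd, rel=0.05)

    def test_second_order_exceeds_first_order(self, make_hset):
        h = make_hset([0.1, 0.2], [0.02, 0.02], [0.05, 0.1], [0.01, 0.01])
        first = wald_ratios(h, se_order="first").se
        second = wald_ratios(h, se_order="second").se
        assert np.all(second > first)


def wls_through_origin_oracle(bx, by, sy):
    """Independent IVW oracle: statsmodels WLS of by on bx, no intercept."""
    import statsmodels.api as sm
    fit = sm.WLS(by, np.asarray(bx)[:, None], weights=1.0 / np.asarray(sy) ** 2).fit()
    return float(fit.params[0])


class TestIVW:
    def test_concordant_instruments(self, make_ratio_hset):
        h = make_ratio_hset([0.5, 0.5], [0.1, 0.2])
        est, het = ivw(h)
        assert est.beta == pytest.approx(0.5)
        assert het.cochran_q == pytest.approx(0.0)

    def test_equal_weights_mean_and_wls_oracle(self, make_hset):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.02, 0.05, 0.08])
        sy = np.array([0.01, 0.01, 0.01])
        h = make_hset(bx, [1e-9] * 3, by, sy)
        est, het = ivw(h, model="fixed")
        assert est.beta == pytest.approx(0.5)
        assert est.beta == pytest.approx(
            wls_through_origin_oracle(bx, by, sy), abs=1e-10)
        # Q against its definitional formula on the ratios
        theta, se = by / bx, sy / bx
        q = np.sum((theta - est.beta) ** 2 / se**2)
        assert het.cochran_q == pytest.approx(q, rel=1e-12)

    def test_matches_wls_oracle_on_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            j = rng.integers(2, 12)
            bx = rng.uniform(0.05, 0.5, j) * rng.choice([-1, 1], j)
            by = rng.normal(0, 0.1, j)
            sy = rng.uniform(0.01, 0.2, j)
            h = build_hset(bx, np.full(j, 0.01), by, sy)
            est, _ = ivw(h, model="fixed")
            assert est.beta == pytest.approx(
                wls_through_origin_oracle(bx, by, sy), abs=1e-10)

    def test_j2_equals_weighted_average_of_ratios(self, make_ratio_hset):
        h = make_ratio_hset([0.2, 0.8], [0.1, 0.3])
        est, _ = ivw(h)
        w = np.array([1 / 0.1**2, 1 / 0.3**2])
        assert est.beta == pytest.approx(
            np.sum(w * [0.2, 0.8]) / w.sum(), rel=1e-12)
        assert est.method == "ivw-fixed"  # auto picks fixed for J < 4

    def test_reorientation_invariance(self, make_hset):
        bx = np.array([0.1, -0.2, 0.15, 0.3])
        by = np.array([0.05, 0.1, -0.08, 0.02])
        sy = np.array([0.01, 0.02, 0.01, 0.03])
        h = make_hset(bx, [0.01] * 4, by, sy)
        flip = np.array([1, -1, -1, 1])
        h2 = make_hset(bx * flip, [0.01] * 4, by * flip, sy)
        for model in ("fixed", "random"):
            a, _ = ivw(h, model=model)
            b, _ = ivw(h2, model=model)
            assert a.beta == pytest.approx(b.beta, rel=1e-12)
            assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_random_effects_never_narrower_than_fixed(self, make_ratio_hset):
        h = make_ratio_hset([0.2, 0.5, 0.8, 1.1], [0.1, 0.1, 0.1, 0.1])
        fixed, _ = ivw(h, model="fixed")
        random_, _ = ivw(h, model="random")
        assert random_.se >= fixed.se

    def test_auto_model_switch(self, make_ratio_hset):
        small = make_ratio_hset([0.2, 0.5, 0.8], [0.1] * 3)
        large = make_ratio_hset([0.2, 0.5, 0.8, 1.1], [0.1] * 4)
        assert ivw(small)[0].method == "ivw-fixed"
        assert ivw(large)[0].method == "ivw-random"

    def test_single_instrument_rejected(self, make_ratio_hset):
        h = make_ratio_hset([0.5, 0.6], [0.1, 0.1]).subset(keep=["rs0"])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)

    def test_ci_and_or_consistency(self, make_ratio_hset):
        est, _ = ivw(make_ratio_hset([0.2, 0.5, 0.8], [0.1] * 3))
        assert est.ci_low < est.beta < est.ci_high
        assert est.odds_ratio == pytest.approx(np.exp(est.beta))
        assert est.or_low == pytest.approx(np.exp(est.ci_low))


def weighted_cdf_inversion_oracle(theta, weights):
    """Numerically invert the cumulative-midpoint weighted CDF at 1/2."""
    order = np.argsort(theta)
    th = np.asarray(theta, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    p = np.cumsum(w) - w / 2
    grid = np.linspace(th[0], th[-1], 2_000_001)
    cdf = np.interp(grid, th, p)
    return float(grid[np.argmin(np.abs(cdf - 0.5))])


class TestWeightedMedian:
    def test_equal_weights_midpoint(self, make_ratio_hset):
        h = make_ratio_hset([0.2, 0.5, 0.9], [0.1] * 3)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_degenerate_agreement(self, make_ratio_hset):
        h = make_ratio_hset([0.4, 0.4, 0.4], [0.1, 0.2, 0.3])
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.4)
        assert 0 < est.se < 0.5

    def test_unequal_weights_match_cdf_inversion_oracle(self):
        theta = np.array([0.1, 0.4, 0.7, 1.2])
        se = np.array([0.05, 0.2, 0.1, 0.3])
        point = weighted_median_point(theta, 1.0 / se**2)
        oracle = weighted_cdf_inversion_oracle(theta, 1.0 / se**2)
        assert point == pytest.approx(oracle, abs=1e-5)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            j = rng.integers(3, 15)
            theta = rng.normal(0, 1, j)
            w = rng.uniform(0.1, 10, j)
            assert weighted_median_point(theta, w) == pytest.approx(
                weighted_cdf_inversion_oracle(theta, w), abs=2e-5)

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=11).filter(
        lambda v: len(v) % 2 == 1 and len(set(v)) == len(v)))
    @settings(max_examples=60, deadline=None)
    def test_equal_weights_odd_j_is_plain_median(self, values):
        theta = np.array(values)
        got = weighted_median_point(theta, np.ones_like(theta))
        assert got == pytest.approx(float(np.median(theta)), abs=1e-12)

    def test_bootstrap_reproducible(self, make_ratio_hset):
        h = make_ratio_hset([0.2, 0.5, 0.9, 0.3], [0.1, 0.2, 0.15, 0.1])
        a = weighted_median(h, n_boot=300, seed=7)
        b = weighted_median(h, n_boot=300, seed=7)
        assert a.se == b.se

    def test_preconditions(self, make_ratio_hset):
        h = make_ratio_hset([0.2, 0.5], [0.1, 0.1])
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(h)
        h3 = make_ratio_hset([0.2, 0.5, 0.9], [0.1] * 3)
        with pytest.raises(DomainError):
            weighted_median(h3, n_boot=50)


class TestEgger:
    def test_noiseless_line_recovered_exactly(self, make_hset):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.01 + 0.4 * bx
        h = make_hset(bx, [0.01] * 4, by, [0.05] * 4)
        est, rep = egger(h)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert rep.egger_intercept == pytest.approx(0.01, abs=1e-12)

    def test_orientation_applied_before_fit(self, make_hset):
        bx = np.array([0.1, -0.2, 0.3, 0.4])
        by = 0.01 + 0.4 * bx
        by[1] = -(0.01 + 0.4 * 0.2)  # oriented point sits on the line
        h = make_hset(bx, [0.01] * 4, by, [0.05] * 4)
        est, rep = egger(h)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert rep.egger_intercept == pytest.approx(0.01, abs=1e-12)

    def test_slope_through_origin_equals_ivw(self, make_hset):
        rng = np.random.default_rng(11)
        bx = rng.uniform(0.05, 0.4, 6)
        by = rng.normal(0.3 * bx, 0.02)
        sy = rng.uniform(0.01, 0.05, 6)
        h = make_hset(bx, [1e-9] * 6, by, sy)
        ivw_beta = ivw(h, model="fixed")[0].beta
        w = 1.0 / sy**2
        origin_slope = np.sum(w * bx * by) / np.sum(w * bx * bx)
        assert origin_slope == pytest.approx(ivw_beta, rel=1e-10)

    def test_null_intercept_pvalues_uniform(self, make_hset):
        # 500 seeded null datasets; KS distance to uniform < 0.1
        J = 10
        bx0 = np.linspace(0.05, 0.3, J)
        sy = np.full(J, 0.05)
        rng = np.random.default_rng(12345)
        ps = []
        for _ in range(500):
            by = 0.4 * bx0 + rng.normal(0, sy)
            _, rep = egger(make_hset(bx0, [1e-6] * J, by, sy))
            ps.append(rep.egger_intercept_pval)
        ps = np.sort(ps)
        ks = np.max(np.abs(ps - np.arange(1, 501) / 500))
        assert ks < 0.1

    def test_detects_directional_pleiotropy(self, make_hset):
        rng = np.random.default_rng(3)
        bx = np.linspace(0.1, 0.5, 8)
        by = 0.08 + 0.3 * bx + rng.normal(0, 0.005, 8)
        _, rep = egger(make_hset(bx, [0.01] * 8, by, [0.02] * 8))
        assert rep.egger_intercept_pval < 0.05

    def test_needs_three_instruments(self, make_ratio_hset):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_ratio_hset([0.2, 0.5], [0.1, 0.1]))


class TestI2GX:
    def test_no_dispersion_clamps_to_zero(self, make_hset):
        h = make_hset([0.1] * 4, [0.01] * 4, [0.05] * 4, [0.01] * 4)
        assert i2_gx(h) == 0.0

    def test_matches_direct_formula_oracle(self, make_hset):
        # spreadsheet-style evaluation of Q_GX and the clamped ratio
        bx = np.array([0.05, 0.10, 0.20])
        sx = np.array([0.005, 0.005, 0.005])
        w = 1.0 / sx**2
        mu = np.sum(w * bx) / np.sum(w)
        q = np.sum(w * (bx - mu) ** 2)
        expected = max(0.0, (q - 2) / q)
        h = make_hset(bx, sx, [0.01, 0.02, 0.04], [0.01] * 3)
        assert i2_gx(h) == pytest.approx(expected, rel=1e-12)

    def test_orientation_invariant(self, make_hset):
        bx = np.array([0.05, -0.10, 0.20])
        h1 = make_hset(bx, [0.005] * 3, [0.01] * 3, [0.01] * 3)
        h2 = make_hset(np.abs(bx), [0.005] * 3, [0.01] * 3, [0.01] * 3)
        assert i2_gx(h1) == pytest.approx(i2_gx(h2))

    def test_bounded_and_monotone_in_se_inflation(self, make_hset):
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.02, 0.3, 6)
        sx = rng.uniform(0.004, 0.02, 6)
        values = []
        for factor in (1.0, 2.0, 4.0, 8.0):
            h = make_hset(bx, sx * factor, [0.01] * 6, [0.01] * 6)
            v = i2_gx(h)
            assert 0.0 <= v <= 1.0
            values.append(v)
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestSimexEgger:
    def test_negligible_exposure_error_returns_naive(self, make_hset):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.01 + 0.4 * bx
        h = make_hset(bx, [1e-12] * 4, by, [0.05] * 4)
        naive, _ = egger(h)
        sim = simex_egger(h, n_sim=500, seed=0)
        assert sim.beta == pytest.approx(naive.beta, abs=1e-6)

    def test_reduces_dilution_bias_vs_naive(self):
        # generative truth: diluted Egger scenario, 200 seeded runs;
        # SIMEX must be closer to the true slope in >= 90% of them
        J, theta = 50, 0.5
        b = np.linspace(0.2, 0.6, J)
        wins = 0
        for r in range(200):
            rg = np.random.default_rng(1000 + r)
            bx = rg.normal(b, 0.1)
            by = rg.normal(theta * b, 0.01)
            bx = np.where(bx == 0, 1e-9, bx)
            h = build_hset(bx, [0.1] * J, by, [0.01] * J)
            naive, _ = egger(h)
            sim = simex_egger(h, n_sim=200, seed=r)
            wins += abs(sim.beta - theta) < abs(naive.beta - theta)
        assert wins >= 180

    def test_reproducible_given_seed(self, make_hset):
        rng = np.random.default_rng(21)
        bx = rng.uniform(0.1, 0.5, 8)
        by = rng.normal(0.3 * bx, 0.02)
        h = make_hset(bx, [0.05] * 8, by, [0.02] * 8)
        a = simex_egger(h, n_sim=300, seed=4)
        b = simex_egger(h, n_sim=300, seed=4)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_needs_three_instruments(self, make_ratio_hset):
        with pytest.raises(InsufficientInstrumentsError):
            simex_egger(make_ratio_hset([0.2, 0.5], [0.1, 0.1]))
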