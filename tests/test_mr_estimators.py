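"""The five MR estimators against independent oracles and invariants."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrmediation.summary_data import HarmonizedSet
from mrmediation.mr_estimators import (
    MethodConfig,
    egger,
    ivw,
    mode_estimators,
    run_all_methods,
    wald_ratio,
    weighted_median,
)


def scale_hset(hset, cx=1.0, cy=1.0):
    r = hset.rows.copy()
    r["beta_x"] *= cx
    r["se_x"] *= abs(cx)
    r["beta_y"] *= cy
    r["se_y"] *= abs(cy)
    return HarmonizedSet(hset.exposure_id, hset.outcome_id, r)


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(0.1, 0.02, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        assert wald_ratio(0.1, 0.02, 0.0, 0.01).beta == 0.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError, match="beta_x = 0"):
            wald_ratio(0.0, 0.02, 0.05, 0.01)

    def test_random_rows_match_oracle(self, rng):
        for _ in range(50):
            bx = float(rng.normal(0.2, 0.1)) or 0.1
            by, sy = float(rng.normal(0, 0.1)), float(rng.uniform(0.005, 0.05))
            est = wald_ratio(bx, 0.02, by, sy)
            assert est.beta == pytest.approx(by / bx, rel=1e-14)
            assert est.se == pytest.approx(abs(sy / bx), rel=1e-14)


class TestIVW:
    def test_two_identical_rows_degenerate_to_wald(self):
        h = HarmonizedSet.from_arrays([0.1, 0.1], [0.02, 0.02],
                                      [0.05, 0.05], [0.01, 0.01])
        assert ivw(h).beta == pytest.approx(0.5, rel=1e-14)

    def test_all_zero_outcome_betas(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2, 0.3], [0.02] * 3,
                                      [0.0] * 3, [0.01] * 3)
        assert ivw(h).beta == 0.0

    def test_single_snp_rejected(self):
        h = HarmonizedSet.from_arrays([0.1], [0.02], [0.05], [0.01])
        with pytest.raises(ValueError, match="at least 2 SNPs"):
            ivw(h)

    def test_matches_wls_through_origin_oracle(self, random_hset):
        bx, _, by, sy = random_hset.arrays()
        fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
        est = ivw(random_hset, mode="fixed")
        assert est.beta == pytest.approx(float(fit.params[0]), rel=1e-12)

    def test_fixed_variance_closed_form(self, random_hset):
        bx, _, by, sy = random_hset.arrays()
        est = ivw(random_hset, mode="fixed")
        assert est.se**2 == pytest.approx(1.0 / np.sum(bx**2 / sy**2), rel=1e-12)

    def test_random_effects_se_never_below_fixed(self, random_hset):
        assert ivw(random_hset, "multiplicative_random").se >= ivw(random_hset, "fixed").se


class TestEgger:
    def test_exact_line_recovered(self, exact_line_hset):
        slope, intercept = egger(exact_line_hset)
        assert slope.beta == pytest.approx(0.5, rel=1e-12)
        assert intercept.beta == pytest.approx(0.01, rel=1e-10)

    def test_matches_weighted_regression_oracle(self, random_hset):
        bx, _, by, sy = random_hset.arrays()
        sign = np.where(bx >= 0, 1.0, -1.0)
        bxo, byo = sign * bx, sign * by
        fit = sm.WLS(byo, sm.add_constant(bxo), weights=1.0 / sy**2).fit()
        slope, intercept = egger(random_hset)
        assert slope.beta == pytest.approx(float(fit.params[1]), rel=1e-12)
        assert intercept.beta == pytest.approx(float(fit.params[0]), rel=1e-12)
        # statsmodels always applies the residual scale; the floor at 1
        # means our SE can only match or exceed it
        if fit.scale >= 1:
            assert slope.se == pytest.approx(float(fit.bse[1]), rel=1e-10)
        else:
            assert slope.se >= float(fit.bse[1])

    def test_two_snps_rejected(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2], [0.02] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(ValueError, match="at least 3"):
            egger(h)


def oracle_weighted_median(ratios, weights):
    """Independent cumulative-weight interpolation, plain Python."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    points = []
    for r, w in pairs:
        points.append((cum + w / 2 - 0.0, r))  # midpoint of this weight slab
        cum += w
    points = [(s / total, r) for s, r in points]
    if 0.5 <= points[0][0]:
        return points[0][1]
    for (s0, r0), (s1, r1) in zip(points, points[1:]):
        if s0 <= 0.5 <= s1:
            return r0 + (r1 - r0) * (0.5 - s0) / (s1 - s0)
    return points[-1][1]


class TestWeightedMedian:
    def test_equal_weights_is_plain_interpolated_median(self):
        h = HarmonizedSet.from_arrays([1.0, 1.0, 1.0], [0.01] * 3,
                                      [0.1, 0.2, 0.9], [0.05] * 3)
        assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(0.2)

    def test_constant_ratios_return_constant(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2, 0.4], [0.01] * 3,
                                      [0.05, 0.10, 0.20], [0.01, 0.03, 0.002])
        assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(0.5, rel=1e-12)

    def test_seven_row_unequal_weights_match_oracle(self, rng):
        bx = rng.uniform(0.1, 0.5, 7)
        sy = rng.uniform(0.005, 0.05, 7)
        by = 0.3 * bx + rng.normal(0, sy)
        h = HarmonizedSet.from_arrays(bx, np.full(7, 0.02), by, sy)
        ratios = by / bx
        weights = (bx / sy) ** 2
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(oracle_weighted_median(ratios, weights), rel=1e-10)

    def test_bootstrap_seeded_reproducible(self, random_hset):
        a = weighted_median(random_hset, n_boot=200, seed=9)
        b = weighted_median(random_hset, n_boot=200, seed=9)
        assert (a.beta, a.se) == (b.beta, b.se)


class TestModes:
    def test_dominant_cluster_wins_simple_mode(self):
        h = HarmonizedSet.from_arrays([1.0] * 4, [0.01] * 4,
                                      [0.5, 0.5, 0.5, 5.0], [0.05] * 4)
        est = mode_estimators(h, "simple", n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_constant_ratios_return_constant(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2, 0.4], [0.01] * 3,
                                      [0.07, 0.14, 0.28], [0.01, 0.02, 0.03])
        for kind in ("simple", "weighted"):
            assert mode_estimators(h, kind, n_boot=20, seed=1).beta == pytest.approx(0.7, rel=1e-9)

    def test_two_cluster_weight_separation(self):
        # larger cluster A at 0.1 with low weight; small cluster B at 0.5
        # with overwhelming weight
        bx = np.ones(8)
        by = np.array([0.08, 0.09, 0.10, 0.11, 0.12, 0.49, 0.50, 0.51])
        sy = np.array([0.1] * 5 + [0.005] * 3)
        h = HarmonizedSet.from_arrays(bx, np.full(8, 0.01), by, sy)
        simple = mode_estimators(h, "simple", n_boot=50, seed=2).beta
        weighted = mode_estimators(h, "weighted", n_boot=50, seed=2).beta
        assert abs(simple - 0.10) < 0.05
        assert abs(weighted - 0.50) < 0.05


class TestRunAll:
    def test_two_snp_set_flags_three_snp_methods(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2], [0.02] * 2, [0.05, 0.1], [0.01] * 2)
        ests = run_all_methods(h, MethodConfig(include_wald_ratios=True))
        by_method = {e.method: e for e in ests if e.method != "wald_ratio"}
        assert by_method["ivw"].ok
        for m in ("egger_slope", "weighted_median", "simple_mode", "weighted_mode"):
            assert by_method[m].extras.get("flag") == "insufficient_instruments"
        assert sum(e.method == "wald_ratio" for e in ests) == 2

    def test_noise_free_data_all_methods_agree(self):
        bx = np.array([0.1, 0.15, 0.2, 0.3, 0.4])
        h = HarmonizedSet.from_arrays(bx, np.full(5, 0.02), 0.25 * bx, np.full(5, 0.01))
        ests = run_all_methods(h, MethodConfig(n_boot=50))
        for e in ests:
            if e.method == "egger_intercept":
                assert e.beta == pytest.approx(0.0, abs=1e-12)
            else:
                assert e.beta == pytest.approx(0.25, rel=1e-6)

    def test_deterministic_given_seed(self, random_hset):
        cfg = MethodConfig(n_boot=100, seed=3)
        a = run_all_methods(random_hset, cfg)
        b = run_all_methods(random_hset, cfg)
        assert [(e.beta, e.se, e.pvalue) for e in a] == [(e.beta, e.se, e.pvalue) for e in b]


class TestEquivariance:
    def test_scale_equivariance(self, random_hset):
        c = 2.5
        scaled = scale_hset(random_hset, cx=c)
        assert ivw(scaled).beta == pytest.approx(ivw(random_hset).beta / c, rel=1e-10)
        assert egger(scaled)[0].beta == pytest.approx(egger(random_hset)[0].beta / c, rel=1e-10)
        assert weighted_median(scaled, 50, 1).beta == pytest.approx(
            weighted_median(random_hset, 50, 1).beta / c, rel=1e-10)
        assert mode_estimators(scaled, "weighted", 1.0, 50, 1).beta == pytest.approx(
            mode_estimators(random_hset, "weighted", 1.0, 50, 1).beta / c, rel=1e-6)

    def test_sign_equivariance(self, random_hset):
        flipped = scale_hset(random_hset, cy=-1.0)
        assert ivw(flipped).beta == pytest.approx(-ivw(random_hset).beta, rel=1e-12)
        assert egger(flipped)[0].beta == pytest.approx(-egger(random_hset)[0].beta, rel=1e-12)
        assert weighted_median(flipped, 50, 1).beta == pytest.approx(
            -weighted_median(random_hset, 50, 1).beta, rel=1e-10)
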