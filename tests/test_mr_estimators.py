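"""Estimators against independent oracles, frozen examples, and invariants."""

import math

import numpy as np
import pytest
from scipy import stats

from estro_mr.errors import (
    ConfigurationError,
    InsufficientDataError,
    RoutingError,
    ValidationError,
)
from estro_mr.mr_estimators import (
    Z_975,
    RatioSet,
    ivw,
    mode_estimate,
    mr_egger,
    p_from_ci,
    wald_ratio,
    weighted_median,
)

from conftest import make_pair


def random_pairs(rng, L, theta=0.5, intercept=0.0):
    bx = rng.uniform(0.02, 0.3, L) * rng.choice([-1, 1], L)
    sy = rng.uniform(0.005, 0.05, L)
    by = intercept * np.sign(bx) + theta * bx + rng.normal(0, sy)
    return [
        make_pair(bx[j], by[j], sy[j], sx=0.002, rsid=f"rs{j}") for j in range(L)
    ]


# ---------------------------------------------------------------- oracles


def ivw_oracle(pairs):
    """Weighted least squares through the origin via the normal equation."""
    bx = np.array([p.beta_exposure for p in pairs])
    by = np.array([p.beta_outcome for p in pairs])
    w = np.array([p.se_outcome for p in pairs]) ** -2.0
    beta = np.sum(w * bx * by) / np.sum(w * bx * bx)
    se = np.sum(w * bx * bx) ** -0.5
    return beta, se


def egger_oracle(pairs):
    """Weighted least squares with intercept via the stacked normal equation,
    after orienting exposure effects positive."""
    bx = np.array([p.beta_exposure for p in pairs])
    by = np.array([p.beta_outcome for p in pairs])
    sy = np.array([p.se_outcome for p in pairs])
    s = np.sign(bx)
    x, y, w = bx * s, by * s, sy**-2.0
    sw, swx, swxx = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = y - intercept - slope * x
    scale = max(1.0, float((w * resid**2).sum()) / (len(pairs) - 2))
    se_slope = math.sqrt(scale * sw / det)
    se_int = math.sqrt(scale * swxx / det)
    return intercept, slope, se_int, se_slope


def weighted_quantile_oracle(theta, weights, q=0.5):
    order = np.argsort(theta)
    th, w = np.asarray(theta)[order], np.asarray(weights)[order]
    w = w / w.sum()
    cum = np.cumsum(w) - w / 2
    return float(np.interp(q, cum, th))


def mode_grid_oracle(theta, weights, bandwidth_factor=1.0):
    """Iteratively refined grid search over the smoothed ratio density."""
    th = np.asarray(theta, float)
    w = (
        np.full(len(th), 1.0 / len(th))
        if weights is None
        else np.asarray(weights, float) / np.sum(weights)
    )
    sd = np.std(th, ddof=1)
    mad = 1.4826 * np.median(np.abs(th - np.median(th)))
    h = bandwidth_factor * 0.9 * min(s for s in (sd, mad) if s > 0) * len(th) ** -0.2
    lo, hi = th.min() - 3 * h, th.max() + 3 * h
    for _ in range(6):
        grid = np.linspace(lo, hi, 2001)
        dens = np.exp(-0.5 * ((grid[:, None] - th) / h) ** 2) @ w
        i = int(np.argmax(dens))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 2000)]
    return float(grid[i])


# ----------------------------------------------------------------- tests


class TestWaldRatio:
    def test_forced_arithmetic(self):
        est = wald_ratio(make_pair(0.020, 0.010, 0.002))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)
        assert est.ci_low == pytest.approx(0.304, abs=5e-4)
        assert est.ci_high == pytest.approx(0.696, abs=5e-4)

    def test_null_outcome_gives_p_one(self):
        est = wald_ratio(make_pair(0.02, 0.0, 0.002))
        assert est.beta == 0.0
        assert est.p == 1.0

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValidationError):
            wald_ratio(make_pair(0.0, 0.01, 0.002))

    def test_published_single_variant_row_recovered(self):
        """A pair built from the published ERβ/AD row reproduces its printed
        estimate, CI and p."""
        bx = -0.021
        est = wald_ratio(make_pair(bx, 0.348 * bx, 0.57169 * abs(bx)))
        assert est.beta == pytest.approx(0.348)
        assert est.ci_low == pytest.approx(-0.773, abs=1e-3)
        assert est.ci_high == pytest.approx(1.468, abs=1e-3)
        assert est.p == pytest.approx(0.543, abs=1e-3)

    def test_second_order_se_is_larger(self):
        pair = make_pair(0.02, 0.01, 0.002, sx=0.005)
        assert wald_ratio(pair, second_order=True).se > wald_ratio(pair).se


class TestIVW:
    def test_two_identical_pairs(self):
        pairs = [make_pair(1.0, 0.5, 1.0, rsid="rs1"), make_pair(1.0, 0.5, 1.0, rsid="rs2")]
        est = ivw(pairs)
        assert est.beta == pytest.approx(0.5)
        assert est.q_stat == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("L", [3, 7, 20, 50])
    def test_matches_normal_equation_oracle(self, L):
        rng = np.random.default_rng(L)
        pairs = random_pairs(rng, L)
        beta, se_fixed = ivw_oracle(pairs)
        fixed = ivw(pairs, effects_model="fixed")
        assert fixed.beta == pytest.approx(beta, abs=1e-10)
        assert fixed.se == pytest.approx(se_fixed, abs=1e-10)
        random = ivw(pairs, effects_model="multiplicative_random")
        assert random.beta == pytest.approx(beta, abs=1e-10)
        assert random.se == pytest.approx(
            se_fixed * max(1.0, math.sqrt(random.q_stat / (L - 1))), abs=1e-10
        )

    def test_single_pair_routing_error(self):
        with pytest.raises(RoutingError):
            ivw([make_pair(0.02, 0.01, 0.002)])

    def test_bypassed_routing_equals_wald(self):
        pair = make_pair(0.02, 0.013, 0.002)
        est = ivw([pair], effects_model="fixed", min_variants=1)
        wald = wald_ratio(pair)
        assert est.beta == pytest.approx(wald.beta, abs=1e-12)
        assert est.se == pytest.approx(wald.se, abs=1e-12)


class TestEgger:
    def test_exact_proportional_fit(self):
        pairs = [make_pair(x, 0.3 * x, 0.01, rsid=f"rs{x}") for x in (0.02, 0.05, 0.08, 0.11)]
        slope, intercept = mr_egger(pairs)
        assert slope.beta == pytest.approx(0.3, abs=1e-10)
        assert intercept.beta == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine_fit(self):
        pairs = [make_pair(x, 0.05 + 0.3 * x, 0.01, rsid=f"rs{x}") for x in (0.02, 0.05, 0.08, 0.11)]
        slope, intercept = mr_egger(pairs)
        assert slope.beta == pytest.approx(0.3, abs=1e-10)
        assert intercept.beta == pytest.approx(0.05, abs=1e-10)

    @pytest.mark.parametrize("L", [3, 7, 25, 50])
    def test_matches_normal_equation_oracle(self, L):
        rng = np.random.default_rng(100 + L)
        pairs = random_pairs(rng, L, intercept=0.02)
        o_int, o_slope, o_se_int, o_se_slope = egger_oracle(pairs)
        slope, intercept = mr_egger(pairs)
        assert slope.beta == pytest.approx(o_slope, abs=1e-10)
        assert intercept.beta == pytest.approx(o_int, abs=1e-10)
        assert slope.se == pytest.approx(o_se_slope, abs=1e-10)
        assert intercept.se == pytest.approx(o_se_int, abs=1e-10)
        # t-based inference with L-2 degrees of freedom
        assert slope.p == pytest.approx(
            2 * stats.t.sf(abs(o_slope) / o_se_slope, L - 2), abs=1e-12
        )

    def test_too_few_variants(self):
        with pytest.raises(InsufficientDataError):
            mr_egger([make_pair(0.02, 0.01, 0.002)] * 2)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        pairs = [make_pair(1.0, r, 1.0, rsid=f"rs{r}") for r in (0.1, 0.5, 0.9)]
        assert weighted_median(pairs, n_boot=10, seed=0).beta == pytest.approx(0.5)

    def test_dominant_weight_pins_the_median(self):
        # first variant holds >50% of total inverse-variance weight
        pairs = [
            make_pair(1.0, 0.9, 0.01, rsid="rs_big"),
            make_pair(1.0, 0.1, 0.5, rsid="rs_a"),
            make_pair(1.0, 0.2, 0.5, rsid="rs_b"),
        ]
        ratios = RatioSet.from_pairs(pairs)
        oracle = weighted_quantile_oracle(ratios.theta, ratios.weights)
        est = weighted_median(pairs, n_boot=10, seed=0)
        assert est.beta == pytest.approx(oracle, abs=1e-6)
        assert abs(est.beta - 0.9) < 0.01

    @pytest.mark.parametrize("L", [3, 10, 30])
    def test_matches_weighted_quantile_oracle(self, L):
        rng = np.random.default_rng(200 + L)
        pairs = random_pairs(rng, L)
        ratios = RatioSet.from_pairs(pairs)
        est = weighted_median(pairs, n_boot=10, seed=0)
        assert est.beta == pytest.approx(
            weighted_quantile_oracle(ratios.theta, ratios.weights), abs=1e-6
        )

    def test_seeded_bootstrap_reproducible(self):
        rng = np.random.default_rng(7)
        pairs = random_pairs(rng, 10)
        a = weighted_median(pairs, n_boot=200, seed=5)
        b = weighted_median(pairs, n_boot=200, seed=5)
        c = weighted_median(pairs, n_boot=200, seed=6)
        assert a.se == b.se
        assert c.se != a.se
        assert c.se == pytest.approx(a.se, rel=0.5)  # Monte-Carlo agreement

    def test_nonpositive_bootstrap_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ConfigurationError):
            weighted_median(random_pairs(rng, 5), n_boot=0)


class TestMode:
    def test_repeated_ratio_dominates(self):
        pairs = [make_pair(1.0, r, 1.0, rsid=f"rs{i}") for i, r in enumerate((0.5, 0.5, 0.5, 2.0))]
        est = mode_estimate(pairs, "simple", n_boot=10, seed=0)
        ratios = RatioSet.from_pairs(pairs)
        assert est.beta == pytest.approx(mode_grid_oracle(ratios.theta, None), abs=1e-6)
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_identical_ratios_exact(self):
        pairs = [make_pair(1.0, 0.7, s, rsid=f"rs{s}") for s in (0.1, 0.2, 0.3)]
        assert mode_estimate(pairs, "weighted", n_boot=10, seed=0).beta == 0.7

    def test_weighted_equals_simple_under_equal_weights(self):
        pairs = [make_pair(1.0, r, 0.05, rsid=f"rs{r}") for r in (0.1, 0.4, 0.45, 0.9)]
        w = mode_estimate(pairs, "weighted", n_boot=10, seed=0)
        s = mode_estimate(pairs, "simple", n_boot=10, seed=0)
        assert w.beta == pytest.approx(s.beta, abs=1e-10)

    @pytest.mark.parametrize("weighting", ["simple", "weighted"])
    @pytest.mark.parametrize("L", [5, 15])
    def test_matches_grid_search_oracle(self, weighting, L):
        rng = np.random.default_rng(300 + L)
        pairs = random_pairs(rng, L)
        ratios = RatioSet.from_pairs(pairs)
        weights = ratios.weights if weighting == "weighted" else None
        est = mode_estimate(pairs, weighting, n_boot=10, seed=0)
        assert est.beta == pytest.approx(mode_grid_oracle(ratios.theta, weights), abs=1e-6)

    def test_nonpositive_bandwidth_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ConfigurationError):
            mode_estimate(random_pairs(rng, 5), bandwidth_factor=0.0)


class TestPFromCI:
    @pytest.mark.parametrize(
        "beta,lo,hi,expected",
        [
            (-1.889, -4.596, 0.819, 0.172),  # published anxiety Wald row
            (-0.192, -0.338, -0.046, 0.010),  # published hippocampal IVW row
            (0.0, -1.0, 1.0, 1.0),
        ],
    )
    def test_recovers_printed_p(self, beta, lo, hi, expected):
        assert p_from_ci(beta, lo, hi) == pytest.approx(expected, abs=1e-3)

    def test_degenerate_ci_rejected(self):
        with pytest.raises(ValidationError):
            p_from_ci(0.1, 0.5, 0.5)


class TestInvariants:
    @pytest.fixture()
    def pairs(self):
        return random_pairs(np.random.default_rng(99), 9)

    def test_scale_equivariance(self, pairs):
        c = 2.5
        scaled = [
            make_pair(
                p.beta_exposure, c * p.beta_outcome, c * p.se_outcome,
                sx=p.se_exposure, rsid=p.rsid,
            )
            for p in pairs
        ]
        for est_fn in (
            lambda ps: ivw(ps),
            lambda ps: mr_egger(ps)[0],
            lambda ps: weighted_median(ps, n_boot=50, seed=3),
            lambda ps: mode_estimate(ps, "weighted", n_boot=50, seed=3),
        ):
            a, b = est_fn(pairs), est_fn(scaled)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-6)
            assert b.se == pytest.approx(c * a.se, rel=1e-4)

    def test_exposure_flip_antisymmetry(self, pairs):
        # re-orienting the exposure definition negates every exposure beta
        flipped = [
            make_pair(-p.beta_exposure, p.beta_outcome, p.se_outcome,
                      sx=p.se_exposure, rsid=p.rsid)
            for p in pairs
        ]
        for method in (
            lambda ps: ivw(ps),
            lambda ps: wald_ratio(ps[0]),
            lambda ps: mr_egger(ps)[0],
        ):
            a, b = method(pairs), method(flipped)
            assert b.beta == pytest.approx(-a.beta, abs=1e-12)
            assert b.p == pytest.approx(a.p, rel=1e-9)

    def test_point_estimates_invariant_to_ordering(self, pairs):
        perm = pairs[::-1]
        assert weighted_median(perm, n_boot=10, seed=0).beta == pytest.approx(
            weighted_median(pairs, n_boot=10, seed=0).beta, abs=1e-12
        )
        assert mode_estimate(perm, "weighted", n_boot=10, seed=0).beta == pytest.approx(
            mode_estimate(pairs, "weighted", n_boot=10, seed=0).beta, abs=1e-9
        )
        assert ivw(perm).beta == pytest.approx(ivw(pairs).beta, abs=1e-14)

    def test_ci_uses_exact_normal_quantile(self, pairs):
        est = ivw(pairs)
        assert est.ci_high - est.beta == pytest.approx(Z_975 * est.se, abs=1e-12)
        assert Z_975 == pytest.approx(1.959964, abs=1e-6)
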