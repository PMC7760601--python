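import itertools
import math

import numpy as np
import pytest

from batchequiv import (
    DEFAULT_LIMITS,
    Scenario,
    bootstrap_gmr_ci,
    equivalence_decision,
    experiment_to_tidy,
    format_limits_percent,
    geometric_mean_ratio,
    simulate_one,
)
from batchequiv.simulate import bootstrap_rng


def type7_quantile(values, q):
    """Independent pure-python linear-interpolation (type 7) quantile oracle."""
    xs = sorted(values)
    n = len(xs)
    h = (n - 1) * q
    lo = math.floor(h)
    if lo >= n - 1:
        return xs[-1]
    return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])


class TestGeometricMeanRatio:
    def test_identical_collections_give_unity(self):
        x = [0.8, 1.1, 1.7]
        assert geometric_mean_ratio(x, x) == pytest.approx(1.0)

    def test_elementwise_scaling_equivariance(self):
        ref = np.array([0.9, 1.0, 1.3])
        assert geometric_mean_ratio(1.05 * ref, ref) == pytest.approx(1.05)

    def test_two_point_example(self):
        assert geometric_mean_ratio([1, 4], [1, 1]) == pytest.approx(2.0)

    @pytest.mark.parametrize("bad", [[1.0, 0.0], [1.0, -2.0], []])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            geometric_mean_ratio(bad, [1.0])


class TestEquivalenceDecision:
    @pytest.mark.parametrize(
        "lo, hi, expected",
        [
            (0.95, 1.05, True),
            (0.89, 1.05, False),
            (0.95, 1.12, False),
            (0.90, 1.0 / 0.9, True),  # inclusive comparisons at the limits
        ],
    )
    def test_containment_rule(self, lo, hi, expected):
        assert equivalence_decision(lo, hi) is expected

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            equivalence_decision(1.1, 0.9)


class TestZeroVarianceDegenerate:
    def test_identical_products_point_interval(self):
        s = Scenario(100, 2, 4, 0, 0)
        r = bootstrap_gmr_ci(simulate_one(s, 0, 0), 50, rng=bootstrap_rng(0, s, 0))
        assert (r.ci_lower, r.ci_upper) == (1.0, 1.0)
        assert r.passed

    def test_five_percent_shift_point_interval_inside_limits(self):
        s = Scenario(95, 1, 6, 0, 0)
        r = bootstrap_gmr_ci(simulate_one(s, 0, 0), 50, rng=bootstrap_rng(0, s, 0))
        assert r.ci_lower == pytest.approx(0.95)
        assert r.ci_upper == pytest.approx(0.95)
        assert r.passed


class TestForcedIndicesOracle:
    """Replayable resamples checked against independent order-statistic math."""

    def _toy(self):
        s = Scenario(100, 1, 2, 0, 0)
        e = simulate_one(s, 0, 0)
        ref = np.array([[1.0, 2.0]])
        test = np.array([[1.0, 8.0]])
        return type(e)(ref_values=ref, test_values=test, scenario=s)

    def test_five_forced_resamples_match_hand_computation(self):
        e = self._toy()
        ref_idx = np.array([[0, 0], [0, 1], [1, 1], [0, 1], [1, 0]])
        test_idx = np.array([[0, 1], [0, 0], [1, 1], [1, 1], [0, 1]])
        thetas = []
        for rr, tt in zip(ref_idx, test_idx):
            g_ref = math.exp(np.mean([math.log(e.ref_values.ravel()[i]) for i in rr]))
            g_test = math.exp(np.mean([math.log(e.test_values.ravel()[i]) for i in tt]))
            thetas.append(g_test / g_ref)
        r = bootstrap_gmr_ci(e, alpha=0.05, indices=(ref_idx, test_idx))
        assert r.ci_lower == pytest.approx(type7_quantile(thetas, 0.05), rel=1e-12)
        assert r.ci_upper == pytest.approx(type7_quantile(thetas, 0.95), rel=1e-12)

    def test_full_enumeration_matches_brute_force_distribution(self):
        # all 27 x 27 flat resamples of a 1x3 experiment, exact quantiles
        s = Scenario(100, 1, 3, 0, 0)
        e = simulate_one(s, 0, 0)
        ref = np.array([[0.9, 1.1, 1.4]])
        test = np.array([[0.8, 1.0, 1.6]])
        exp = type(e)(ref_values=ref, test_values=test, scenario=s)
        combos = list(itertools.product(range(3), repeat=3))
        pairs = list(itertools.product(combos, combos))
        ref_idx = np.array([p[0] for p in pairs])
        test_idx = np.array([p[1] for p in pairs])
        brute = [
            math.exp(
                np.mean([math.log(test[0, i]) for i in tt])
                - np.mean([math.log(ref[0, i]) for i in rr])
            )
            for rr, tt in pairs
        ]
        r = bootstrap_gmr_ci(exp, indices=(ref_idx, test_idx))
        assert r.ci_lower == pytest.approx(type7_quantile(brute, 0.05), rel=1e-12)
        assert r.ci_upper == pytest.approx(type7_quantile(brute, 0.95), rel=1e-12)
        assert r.n_bootstrap == 729

    def test_larger_alpha_nests_inside_smaller(self):
        e = self._toy()
        rng = np.random.default_rng(4)
        idx = (rng.integers(0, 2, (40, 2)), rng.integers(0, 2, (40, 2)))
        wide = bootstrap_gmr_ci(e, alpha=0.05, indices=idx)
        narrow = bootstrap_gmr_ci(e, alpha=0.10, indices=idx)
        assert wide.ci_lower <= narrow.ci_lower
        assert narrow.ci_upper <= wide.ci_upper

    def test_scale_shift_multiplies_both_bounds(self):
        s = Scenario(100, 2, 3, 0, 0)
        base = simulate_one(s, 0, 0)
        ref = np.array([[0.9, 1.0, 1.2], [1.1, 0.95, 1.05]])
        test = np.array([[1.0, 1.3, 0.85], [1.15, 0.9, 1.02]])
        rng = np.random.default_rng(11)
        idx = (rng.integers(0, 6, (60, 6)), rng.integers(0, 6, (60, 6)))
        c = 1.07
        r1 = bootstrap_gmr_ci(type(base)(ref_values=ref, test_values=test, scenario=s),
                              indices=idx)
        r2 = bootstrap_gmr_ci(type(base)(ref_values=ref, test_values=c * test, scenario=s),
                              indices=idx)
        assert r2.ci_lower == pytest.approx(c * r1.ci_lower, rel=1e-12)
        assert r2.ci_upper == pytest.approx(c * r1.ci_upper, rel=1e-12)

    def test_relabeling_invariance_on_sorted_data(self):
        # permuting units then sorting restores identical CI under one index stream
        s = Scenario(100, 1, 5, 0, 0)
        base = simulate_one(s, 0, 0)
        ref = np.array([[0.9, 1.0, 1.2, 1.05, 0.97]])
        test = np.array([[1.1, 0.8, 1.0, 1.3, 0.99]])
        perm = np.random.default_rng(1).permutation(5)
        rng = np.random.default_rng(2)
        idx = (rng.integers(0, 5, (50, 5)), rng.integers(0, 5, (50, 5)))
        r1 = bootstrap_gmr_ci(
            type(base)(ref_values=np.sort(ref), test_values=np.sort(test), scenario=s),
            indices=idx)
        r2 = bootstrap_gmr_ci(
            type(base)(ref_values=np.sort(ref[:, perm]), test_values=np.sort(test[:, perm]),
                       scenario=s),
            indices=idx)
        assert (r1.ci_lower, r1.ci_upper) == (r2.ci_lower, r2.ci_upper)


class TestStrategies:
    def test_flat_ci_width_grows_with_variability(self):
        # averaged over 200 experiments, more IBV or ABV widens the flat CI
        def mean_width(ibv, abv):
            s = Scenario(100, 2, 6, ibv, abv)
            widths = []
            for i in range(200):
                e = simulate_one(s, 5, i)
                r = bootstrap_gmr_ci(e, 300, strategy="flat", rng=bootstrap_rng(5, s, i))
                widths.append(r.ci_upper - r.ci_lower)
            return np.mean(widths)

        base = mean_width(2.5, 2.5)
        assert mean_width(15, 2.5) > base
        assert mean_width(2.5, 15) > base

    def test_all_strategies_coincide_in_distribution_at_single_batch(self):
        # same resampling space when N_B = 1: identical CI for identical rng
        s = Scenario(100, 1, 6, 5, 5)
        e = simulate_one(s, 3, 0)
        rs = {
            strat: bootstrap_gmr_ci(e, 400, strategy=strat, rng=bootstrap_rng(3, s, 0))
            for strat in ("flat", "stratified", "hierarchical")
        }
        # flat and stratified draw the same (B, 6) index block from the same stream
        assert rs["flat"].ci_lower == pytest.approx(rs["stratified"].ci_lower, rel=1e-9)
        assert rs["flat"].ci_upper == pytest.approx(rs["stratified"].ci_upper, rel=1e-9)

    def test_hierarchical_wider_than_stratified_with_batch_effects(self):
        s = Scenario(100, 3, 6, 10, 2.5)
        widths = {}
        for strat in ("stratified", "hierarchical"):
            total = 0.0
            for i in range(100):
                e = simulate_one(s, 8, i)
                r = bootstrap_gmr_ci(e, 300, strategy=strat, rng=bootstrap_rng(8, s, i))
                total += r.ci_upper - r.ci_lower
            widths[strat] = total
        assert widths["hierarchical"] > widths["stratified"]


class TestTidyInput:
    def test_tidy_table_equals_experiment_input(self):
        s = Scenario(97.5, 2, 4, 5, 5)
        e = simulate_one(s, 0, 0)
        r_exp = bootstrap_gmr_ci(e, 200, rng=bootstrap_rng(0, s, 0))
        r_df = bootstrap_gmr_ci(experiment_to_tidy(e), 200, rng=bootstrap_rng(0, s, 0))
        assert r_exp.gmr_observed == pytest.approx(r_df.gmr_observed)
        assert r_exp.ci_lower == pytest.approx(r_df.ci_lower)
        assert r_exp.ci_upper == pytest.approx(r_df.ci_upper)

    def test_ragged_batches_rejected(self):
        import pandas as pd

        df = pd.DataFrame({
            "product": ["reference"] * 5 + ["test"] * 4,
            "batch": [1, 1, 1, 2, 2, 1, 1, 2, 2],
            "unit": [1, 2, 3, 1, 2, 1, 2, 1, 2],
            "value": [1.0] * 9,
        })
        with pytest.raises(ValueError, match="ragged"):
            bootstrap_gmr_ci(df, 10, rng=np.random.default_rng(0))

    def test_missing_product_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"product": ["reference"] * 2, "batch": [1, 1],
                           "unit": [1, 2], "value": [1.0, 1.1]})
        with pytest.raises(ValueError, match="test"):
            bootstrap_gmr_ci(df, 10, rng=np.random.default_rng(0))


class TestValidation:
    def test_alpha_out_of_range_rejected(self):
        s = Scenario(100, 1, 3, 0, 0)
        e = simulate_one(s, 0, 0)
        with pytest.raises(ValueError, match="alpha"):
            bootstrap_gmr_ci(e, 10, alpha=0.7, rng=np.random.default_rng(0))

    def test_unknown_strategy_rejected(self):
        e = simulate_one(Scenario(100, 1, 3, 0, 0), 0, 0)
        with pytest.raises(ValueError, match="strategy"):
            bootstrap_gmr_ci(e, 10, strategy="jackknife", rng=np.random.default_rng(0))

    def test_rng_required_without_indices(self):
        e = simulate_one(Scenario(100, 1, 3, 0, 0), 0, 0)
        with pytest.raises(ValueError, match="rng"):
            bootstrap_gmr_ci(e, 10)


def test_default_limits_render_as_ten_percent_range():
    assert format_limits_percent(DEFAULT_LIMITS) == "90.00-111.11%"
    assert DEFAULT_LIMITS[0] * DEFAULT_LIMITS[1] == pytest.approx(1.0, abs=1e-15)
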