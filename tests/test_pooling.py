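"""Step 2: pooling of log-RORs, heterogeneity statistics, subgroups."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metaepi import (
    MAResult,
    i2_confidence_interval,
    i2_from_q,
    interaction_test,
    pool_rors,
    subgroup_analysis,
)


def ma_result(ma_id, log_ror, se, **kw):
    defaults = dict(tau2_within=0.02, k_pc=2, k_st=3)
    defaults.update(kw)
    return MAResult(ma_id=ma_id, log_ror=log_ror, se_log_ror=se, **defaults)


THREE_POINT = [
    ma_result("A", -0.2, 0.1),
    ma_result("B", 0.0, 0.1),
    ma_result("C", 0.2, 0.1),
]


class TestPoolRors:
    def test_two_identical_inputs_are_homogeneous(self):
        p = pool_rors([ma_result("A", -0.3, 0.2), ma_result("B", -0.3, 0.2)])
        assert p.log_ror_combined == pytest.approx(-0.3, abs=1e-12)
        assert p.Q == pytest.approx(0.0, abs=1e-12)
        assert p.i2 == 0.0 and p.tau2_between == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_three_point_fixture_hand_computation(self):
        """log-RORs {-0.2, 0, 0.2}, variances 0.01: Q=8, I2=75%, DL tau2=0.03,
        pooled ROR 1.00 with random-effects weights 25 each."""
        p = pool_rors(THREE_POINT, method="dl")
        assert p.Q == pytest.approx(8.0, abs=1e-10)
        assert p.df == 2
        assert p.i2 == pytest.approx(75.0, abs=1e-10)
        assert p.tau2_between == pytest.approx(0.03, abs=1e-12)
        assert p.log_ror_combined == pytest.approx(0.0, abs=1e-12)
        assert p.se == pytest.approx(math.sqrt(1.0 / 75.0), abs=1e-12)
        assert p.ror == pytest.approx(1.0, abs=1e-12)
        assert p.ci_low == pytest.approx(0.7975, abs=1e-3)
        assert p.ci_high == pytest.approx(1.2540, abs=1e-3)

    def test_single_ma_passthrough_heterogeneity_not_applicable(self):
        p = pool_rors([ma_result("A", -0.3, 0.2)])
        assert p.log_ror_combined == -0.3 and p.k == 1
        assert p.Q is None and p.i2 is None and p.tau2_between is None

    def test_no_inputs_is_an_error(self):
        with pytest.raises(ValueError):
            pool_rors([])

    def test_non_converged_results_excluded(self):
        extra = ma_result("D", 5.0, 0.1, converged=False)
        p = pool_rors(THREE_POINT + [extra], method="dl")
        assert p.k == 3 and p.log_ror_combined == pytest.approx(0.0, abs=1e-12)

    def test_fixed_effect_limit_is_inverse_variance_mean(self):
        rs = [ma_result("A", -0.4, 0.1), ma_result("B", 0.1, 0.3), ma_result("C", -0.2, 0.2)]
        p = pool_rors(rs, method="dl")
        # force tau2 = 0 via the estimator directly
        from metaepi import RandomEffectsMetaAnalysis

        y = np.array([r.log_ror for r in rs])
        v = np.array([r.se_log_ror**2 for r in rs])
        fe = RandomEffectsMetaAnalysis(tau2_fixed=0.0).fit(y, v)
        w = 1.0 / v
        assert fe.effect_ == pytest.approx(float(np.sum(w * y) / np.sum(w)), abs=1e-12)
        assert fe.se_ == pytest.approx(float(np.sqrt(1.0 / np.sum(w))), abs=1e-12)
        assert p.tau2_between >= 0.0

    @given(st.permutations(range(6)))
    @settings(max_examples=50, deadline=None)
    def test_pooled_estimate_order_invariant_and_bracketed(self, perm):
        rs = [
            ma_result(f"M{i}", lr, se)
            for i, (lr, se) in enumerate(
                [(-0.5, 0.2), (-0.1, 0.15), (0.3, 0.4), (0.0, 0.1), (-0.25, 0.3), (0.12, 0.18)]
            )
        ]
        base = pool_rors(rs)
        shuffled = pool_rors([rs[i] for i in perm])
        assert shuffled.log_ror_combined == pytest.approx(base.log_ror_combined, abs=1e-10)
        assert shuffled.tau2_between == pytest.approx(base.tau2_between, abs=1e-10)
        lows = min(r.log_ror for r in rs)
        highs = max(r.log_ror for r in rs)
        assert lows - 1e-12 <= base.log_ror_combined <= highs + 1e-12

    @pytest.mark.parametrize("method", ["reml", "dl"])
    def test_i2_q_identity_holds_on_outputs(self, method):
        rng = np.random.default_rng(5)
        rs = [
            ma_result(f"M{i}", float(rng.normal(0, 0.3)), float(rng.uniform(0.1, 0.5)))
            for i in range(8)
        ]
        p = pool_rors(rs, method=method)
        assert p.i2 == pytest.approx(i2_from_q(p.Q, p.df), abs=1e-12)
        assert p.ci_low <= p.ror <= p.ci_high


class TestI2ConfidenceInterval:
    def test_null_heterogeneity_interval_contains_zero(self):
        low, high = i2_confidence_interval(Q=3.0, df=3)
        assert low == 0.0
        assert 0.0 <= high <= 100.0

    def test_degenerate_q_zero(self):
        assert i2_from_q(0.0, 2) == 0.0
        low, high = i2_confidence_interval(Q=0.0, df=2)
        assert low == 0.0 and high < 100.0

    def test_matches_independent_log_h_formula(self):
        """Q=8, df=2 against a from-scratch evaluation of the ln(H) method."""
        Q, df, k = 8.0, 2, 3
        h = math.sqrt(Q / df)
        se_ln_h = 0.5 * (math.log(Q) - math.log(df)) / (math.sqrt(2 * Q) - math.sqrt(2 * k - 3))
        z = stats.norm.ppf(0.975)
        lo_h = math.exp(math.log(h) - z * se_ln_h)
        hi_h = math.exp(math.log(h) + z * se_ln_h)
        expected = (100 * (lo_h**2 - 1) / lo_h**2, 100 * (hi_h**2 - 1) / hi_h**2)
        got = i2_confidence_interval(Q, df)
        assert got[0] == pytest.approx(expected[0], abs=1e-9)
        assert got[1] == pytest.approx(expected[1], abs=1e-9)

    def test_df_zero_not_applicable(self):
        with pytest.raises(ValueError):
            i2_confidence_interval(1.0, 0)

    def test_truncation_to_unit_interval(self):
        low, high = i2_confidence_interval(Q=200.0, df=2)
        assert 0.0 <= low <= high <= 100.0


class TestInteractionAndSubgroups:
    def test_identical_groups_no_interaction(self):
        q, df, p = interaction_test([0.1, 0.1], [0.2, 0.2])
        assert q == pytest.approx(0.0, abs=1e-12) and df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_two_group_fixture(self):
        q, df, p = interaction_test([0.0, 0.2], [0.1, 0.1])
        assert q == pytest.approx(2.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(0.1573, abs=1e-4)

    def test_three_groups_df_bookkeeping(self):
        rs = [ma_result(f"M{i}", 0.1 * i, 0.2) for i in range(6)]
        labels = {f"M{i}": ["a", "b", "c"][i % 3] for i in range(6)}
        sg = subgroup_analysis(rs, labels)
        assert sg.df_interaction == 2
        assert set(sg.per_group) == {"a", "b", "c"}
        assert 0.0 <= sg.p_interaction <= 1.0

    def test_single_ma_group_still_enters_interaction(self):
        rs = [ma_result("A", -0.2, 0.1), ma_result("B", 0.0, 0.1), ma_result("C", 0.2, 0.1)]
        sg = subgroup_analysis(rs, {"A": "g1", "B": "g1", "C": "g2"})
        assert sg.per_group["g2"].k == 1
        assert sg.per_group["g2"].i2 is None
        assert sg.df_interaction == 1

    def test_all_in_one_group_rejected(self):
        rs = [ma_result("A", -0.2, 0.1), ma_result("B", 0.0, 0.1)]
        with pytest.raises(ValueError):
            subgroup_analysis(rs, {"A": "g", "B": "g"})

    def test_unlabelled_mas_counted_not_fatal(self):
        rs = THREE_POINT
        sg = subgroup_analysis(rs, {"A": "g1", "B": "g2", "C": None})
        assert sg.excluded == {"unlabelled": 1}
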