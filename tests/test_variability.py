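import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstlnc.variability import (
    cv2,
    cv2_permutation_test,
    kinetics_permutation_matched,
    match_expression,
    rank_cv2,
    select_top_variable_lncRNAs,
    subsample_power,
)


class TestCv2:
    def test_constant_vector_is_zero(self):
        assert cv2([4, 4, 4, 4]) == 0.0

    def test_direct_value(self):
        # var = 100/3 (n-1), mean = 5 -> 33.33/25
        assert cv2([0, 0, 10, 10]) == pytest.approx(4.0 / 3.0)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        v = np.array([1.0, 2.0, 5.0, 0.0, 3.0])
        assert cv2(c * v) == pytest.approx(cv2(v))

    def test_zero_mean_undefined(self):
        assert np.isnan(cv2([0, 0, 0]))


class TestMatchExpression:
    def test_nearest_by_absolute_difference(self):
        cand = pd.Series({"a": 1.0, "b": 1.9, "c": 2.05, "d": 3.0})
        assert set(match_expression(2.0, cand, 2)) == {"c", "b"}

    def test_k_equals_pool(self):
        cand = pd.Series({"a": 1.0, "b": 2.0})
        assert set(match_expression(5.0, cand, 2)) == {"a", "b"}

    def test_tie_breaks_to_lower_gene_id(self):
        cand = pd.Series({"b": 2.5, "a": 1.5})  # both |diff| = 0.5 from 2.0
        assert match_expression(2.0, cand, 1) == ["a"]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            match_expression(1.0, pd.Series(dtype=float), 1)


class TestCv2PermutationTest:
    def _setup(self, lnc_vals, cand_vals):
        lnc = pd.Series(lnc_vals, index=[f"l{i}" for i in range(len(lnc_vals))])
        cand = pd.Series(cand_vals, index=[f"m{i}" for i in range(len(cand_vals))])
        matched = {l: list(cand.index) for l in lnc.index}
        return lnc, matched, cand

    def test_all_lnc_above_gives_p_zero(self):
        lnc, matched, cand = self._setup([10, 11, 12], [1, 2, 3])
        res = cv2_permutation_test(lnc, matched, candidate_cv2=cand, n_perm=500, seed=0)
        assert res["p"] == 0.0

    def test_all_lnc_below_gives_p_one(self):
        lnc, matched, cand = self._setup([1, 2, 3], [10, 11, 12])
        res = cv2_permutation_test(lnc, matched, candidate_cv2=cand, n_perm=500, seed=0)
        assert res["p"] == 1.0

    def test_degenerate_ties_flagged_with_p_zero(self):
        lnc, matched, cand = self._setup([5.0, 5.0], [5.0, 5.0])
        with pytest.warns(UserWarning, match="tie"):
            res = cv2_permutation_test(lnc, matched, candidate_cv2=cand,
                                       n_perm=100, seed=0)
        assert res["p"] == 0.0 and res["degenerate"]

    def test_null_p_uniform_on_average(self):
        # exchangeable null: lncRNA CV2s drawn from the same pool as candidates
        rng = np.random.default_rng(0)
        ps = []
        for rep in range(50):
            pool = rng.gamma(2.0, 1.0, 60)
            lnc = pd.Series(pool[:20], index=[f"l{i}" for i in range(20)])
            cand = pd.Series(pool[20:], index=[f"m{i}" for i in range(40)])
            matched = {l: list(cand.index) for l in lnc.index}
            res = cv2_permutation_test(lnc, matched, candidate_cv2=cand,
                                       n_perm=200, seed=rep)
            ps.append(res["p"])
        assert abs(np.mean(ps) - 0.5) < 0.1


class TestRankCv2:
    def _pool(self, n=150, seed=0):
        rng = np.random.default_rng(seed)
        means = pd.Series(rng.uniform(1, 10, n), index=[f"m{i}" for i in range(n)])
        cv2s = pd.Series(rng.gamma(2, 1, n), index=means.index)
        return means, cv2s

    def test_above_all_gives_one(self):
        means, cv2s = self._pool()
        r = rank_cv2(cv2s.max() + 1, 5.0, cv2s, means)
        assert r == 1.0

    def test_below_all_gives_zero(self):
        means, cv2s = self._pool()
        r = rank_cv2(-1.0, 5.0, cv2s, means)
        assert r == 0.0

    def test_insufficient_pool_warns_and_skips(self):
        means, cv2s = self._pool(n=50)
        with pytest.warns(UserWarning):
            assert np.isnan(rank_cv2(1.0, 5.0, cv2s, means))

    def test_monotone_transform_invariance(self):
        means, cv2s = self._pool()
        target = float(np.median(cv2s))
        r1 = rank_cv2(target, 5.0, cv2s, means)
        r2 = rank_cv2(np.log(target), 5.0, np.log(cv2s), means)
        assert r1 == pytest.approx(r2)


class TestSelectTopVariable:
    def test_distinct_ranks_select_largest(self):
        r = pd.Series(np.linspace(0, 1, 60), index=[f"l{i:02d}" for i in range(60)])
        top = select_top_variable_lncRNAs(r, 50)
        assert len(top) == 50
        assert set(top) == set(r.sort_values(ascending=False).index[:50])

    def test_tie_at_cutoff_keeps_lower_id(self):
        r = pd.Series([1.0, 0.5, 0.5], index=["a", "c", "b"])
        top = select_top_variable_lncRNAs(r, 2)
        assert top == ["a", "b"]

    def test_short_pool_returns_all_with_warning(self):
        r = pd.Series([0.1] * 40, index=[f"l{i}" for i in range(40)])
        with pytest.warns(UserWarning):
            assert len(select_top_variable_lncRNAs(r, 50)) == 40


class TestSubsamplePower:
    def _inflated(self, n_lnc=60, seed=0):
        rng = np.random.default_rng(seed)
        lnc = pd.Series(rng.gamma(2, 1, n_lnc) + 4.0,
                        index=[f"l{i}" for i in range(n_lnc)])
        cand = pd.Series(rng.gamma(2, 1, 100), index=[f"m{i}" for i in range(100)])
        matched = {l: list(cand.index) for l in lnc.index}
        return lnc, matched, cand

    def test_strong_inflation_detected_at_full_pool(self):
        lnc, matched, cand = self._inflated()
        curve = subsample_power(lnc, matched, cand, sizes=[60], reps=20,
                                n_perm=200, seed=1)
        assert curve["detected_95"].iloc[0] == 1.0

    def test_null_detection_near_half_on_average(self):
        # the 50% criterion is symmetric under the null when averaged over
        # independent datasets (any single pool is fixed and tips one way)
        rng = np.random.default_rng(3)
        det = []
        for rep in range(12):
            pool = rng.gamma(2, 1, 160)
            lnc = pd.Series(pool[:60], index=[f"l{i}" for i in range(60)])
            cand = pd.Series(pool[60:], index=[f"m{i}" for i in range(100)])
            matched = {l: list(cand.index) for l in lnc.index}
            curve = subsample_power(lnc, matched, cand, sizes=[20], reps=10,
                                    n_perm=200, seed=rep)
            det.append(curve["detected_50"].iloc[0])
        assert 0.25 < np.mean(det) < 0.75


class TestKineticsPermutation:
    def _kin(self, freqs, sizes, prefix):
        return pd.DataFrame({
            "burst_frequency": freqs, "burst_size": sizes,
        }, index=[f"{prefix}{i}" for i in range(len(freqs))])

    def test_lnc_frequencies_far_below_gives_p_zero(self):
        lnc = self._kin([0.25] * 10, [3.0] * 10, "l")
        mrna = self._kin([1.0] * 30, [6.0] * 30, "m")
        matched = {l: list(mrna.index[:10]) for l in lnc.index}
        res = kinetics_permutation_matched(lnc, matched, mrna, n_perm=300, seed=0)
        assert res["p_frequency"] == 0.0

    def test_lnc_sizes_above_all_gives_p_size_zero(self):
        lnc = self._kin([1.0] * 10, [50.0] * 10, "l")
        mrna = self._kin([1.0] * 30, [6.0] * 30, "m")
        matched = {l: list(mrna.index[:10]) for l in lnc.index}
        res = kinetics_permutation_matched(lnc, matched, mrna, n_perm=300, seed=0)
        assert res["p_size"] == 0.0

    def test_identical_distributions_give_half(self):
        rng = np.random.default_rng(5)
        ps_f, ps_s = [], []
        for rep in range(10):
            freqs = rng.gamma(2, 0.5, 80)
            sizes = rng.gamma(3, 2.0, 80)
            lnc = self._kin(freqs[:30], sizes[:30], "l")
            mrna = self._kin(freqs[30:], sizes[30:], "m")
            matched = {l: list(mrna.index) for l in lnc.index}
            res = kinetics_permutation_matched(lnc, matched, mrna, n_perm=300,
                                               seed=rep)
            ps_f.append(res["p_frequency"])
            ps_s.append(res["p_size"])
        assert abs(np.mean(ps_f) - 0.5) < 0.2
        assert abs(np.mean(ps_s) - 0.5) < 0.2
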