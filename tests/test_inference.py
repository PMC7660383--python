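import numpy as np
import pytest

from symte.exceptions import AlignmentError
from symte.inference import (
    GroupMember,
    GroupSpec,
    aggregate_group_te,
    significance,
    strata_codes,
    stratified_permute,
    surrogate_test,
)
from symte.series import BinarySeries
from symte.synthetic import gen_coupled_binary

from .conftest import bs


def iid_member(rng, code="AA", T=228, pop=1e6, q=2):
    mk = lambda: bs(rng.integers(0, 2, T))
    return GroupMember(code, pop, mk(), mk(), tuple(mk() for _ in range(q)))


class TestStratifiedPermute:
    def test_singleton_strata_identity(self, rng):
        cause = bs(rng.integers(0, 2, 10))
        strata = np.arange(9)
        out = stratified_permute(cause, strata, rng)
        assert np.array_equal(out.symbols, cause.symbols)

    def test_one_global_stratum_permutes(self, rng):
        cause = bs([1] * 20 + [0] * 20)
        strata = np.zeros(39, dtype=int)
        out = stratified_permute(cause, strata, rng)
        assert sorted(out.symbols[:-1]) == sorted(cause.symbols[:-1])
        assert out.symbols[-1] == cause.symbols[-1]
        assert not np.array_equal(out.symbols, cause.symbols)  # w.h.p.

    def test_two_strata_admissible_outputs(self, rng):
        # strata {t1,t3} and {t2,t4} with cause (up,down,down,up):
        # only within-stratum swaps are admissible
        cause = bs([1, 0, 0, 1, 0])
        strata = np.array([0, 1, 0, 1])
        admissible = {
            (1, 0, 0, 1),
            (0, 0, 1, 1),
            (1, 1, 0, 0),
            (0, 1, 1, 0),
        }
        seen = set()
        for _ in range(200):
            out = stratified_permute(cause, strata, rng)
            seen.add(tuple(int(v) for v in out.symbols[:4]))
        assert seen <= admissible
        assert len(seen) == 4

    def test_preserves_joint_histogram_with_strata_vars(self, rng):
        T = 60
        effect = bs(rng.integers(0, 2, T))
        z = bs(rng.integers(0, 2, T))
        cause = bs(rng.integers(0, 2, T))
        strata = strata_codes(effect, [z])
        out = stratified_permute(cause, strata, rng)
        before = {}
        after = {}
        for t in range(T - 1):
            key = (cause.symbols[t], effect.symbols[t], z.symbols[t])
            before[key] = before.get(key, 0) + 1
            key2 = (out.symbols[t], effect.symbols[t], z.symbols[t])
            after[key2] = after.get(key2, 0) + 1
        assert before == after

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(AlignmentError):
            stratified_permute(bs([0, 1, 0]), np.zeros(5, dtype=int), rng)


class TestAggregateGroupTe:
    def test_single_state_collapses(self):
        assert aggregate_group_te({"AA": 0.37}, {"AA": 123456.0}) == pytest.approx(0.37)

    def test_all_zero(self):
        assert aggregate_group_te({"AA": 0.0, "BB": 0.0}, {"AA": 1.0, "BB": 2.0}) == 0.0

    def test_two_equal_population_states(self):
        # (p*sqrt(.09) + p*sqrt(.09))^2 / (2 p^2) = 4 * .09 / 2 = .18
        val = aggregate_group_te({"AA": 0.09, "BB": 0.09}, {"AA": 5.0, "BB": 5.0})
        assert val == pytest.approx(0.18)

    def test_population_scale_invariance(self, rng):
        te = {c: float(v) for c, v in zip("abcd", rng.random(4))}
        pop = {c: float(v) for c, v in zip("abcd", rng.uniform(1, 10, 4))}
        base = aggregate_group_te(te, pop)
        scaled = aggregate_group_te(te, {k: 17.3 * v for k, v in pop.items()})
        assert scaled == pytest.approx(base)

    def test_key_mismatch_errors(self):
        with pytest.raises(KeyError):
            aggregate_group_te({"AA": 0.1}, {"BB": 1.0})

    def test_negative_te_errors(self):
        with pytest.raises(ValueError):
            aggregate_group_te({"AA": -0.1}, {"AA": 1.0})


class TestSurrogateTest:
    def test_planted_maximal_coupling_tiny_p(self, rng):
        x, y = gen_coupled_binary(228, 1.0, rng)
        res = surrogate_test(GroupSpec([GroupMember("AA", 1e6, x, y)]), B=200, seed=7)
        assert res.p_value <= 0.005
        assert res.p_string() == "< 0.005"

    def test_b_one(self, rng):
        x, y = gen_coupled_binary(100, 0.0, rng)
        res = surrogate_test(GroupSpec([GroupMember("AA", 1e6, x, y)]), B=1, seed=7)
        assert res.surrogate_values.shape == (1,)
        assert res.p_value in (0.0, 1.0)

    def test_reproducible_under_seed(self, rng):
        members = [iid_member(rng, code) for code in ("AA", "BB", "CC")]
        r1 = surrogate_test(GroupSpec(members), B=50, seed=42)
        r2 = surrogate_test(GroupSpec(members), B=50, seed=42)
        assert np.array_equal(r1.surrogate_values, r2.surrogate_values)
        assert r1.observed == r2.observed

    def test_member_order_invariance(self, rng):
        members = [iid_member(rng, code) for code in ("AA", "BB", "CC")]
        r1 = surrogate_test(GroupSpec(members), B=50, seed=42)
        r2 = surrogate_test(GroupSpec(members[::-1]), B=50, seed=42)
        assert np.allclose(np.sort(r1.surrogate_values), np.sort(r2.surrogate_values))
        assert r1.observed == pytest.approx(r2.observed)

    def test_q95_is_empirical_quantile(self, rng):
        members = [iid_member(rng)]
        res = surrogate_test(GroupSpec(members), B=100, seed=3)
        assert res.q95 == pytest.approx(np.quantile(res.surrogate_values, 0.95))

    def test_degenerate_member_flagged_and_zero(self, rng):
        const = bs([0] * 228)
        effect = bs(rng.integers(0, 2, 228))
        res = surrogate_test(
            GroupSpec([GroupMember("AA", 1e6, const, effect)]), B=20, seed=1
        )
        assert res.degenerate_members == ("AA",)
        assert res.member_observed["AA"] == 0.0

    def test_null_pvalues_roughly_uniform(self):
        # KS sanity check against U(0,1) under a planted null
        from scipy.stats import kstest

        pvals = []
        for s in range(200):
            rng = np.random.default_rng(9000 + s)
            x, y = gen_coupled_binary(228, 0.0, rng)
            res = surrogate_test(
                GroupSpec([GroupMember("AA", 1e6, x, y)]), B=100, seed=s
            )
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec([])

    def test_invalid_b(self, rng):
        x, y = gen_coupled_binary(50, 0.0, rng)
        with pytest.raises(ValueError):
            surrogate_test(GroupSpec([GroupMember("AA", 1e6, x, y)]), B=0)


class TestSignificance:
    def _result(self, p, rng):
        x, y = gen_coupled_binary(50, 0.0, rng)
        res = surrogate_test(GroupSpec([GroupMember("AA", 1e6, x, y)]), B=10, seed=0)
        object.__setattr__(res, "p_value", p)
        return res

    def test_small_p_significant(self, rng):
        assert significance(self._result(0.002, rng))

    def test_boundary_not_significant(self, rng):
        assert not significance(self._result(0.050, rng))

    def test_large_p_not_significant(self, rng):
        assert not significance(self._result(0.954, rng))

    def test_bad_alpha(self, rng):
        with pytest.raises(ValueError):
            significance(self._result(0.01, rng), alpha=1.5)
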