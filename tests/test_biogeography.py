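"""DEC/DIVALIKE(+J) state space, rate matrix, cladogenesis, likelihood,
marginal reconstruction and model comparison."""

import numpy as np
import pytest
from scipy.linalg import expm

from orodiversify.biogeography import (
    GeoParams,
    anagenetic_Q,
    ancestral_ranges,
    build_state_space,
    cladogenesis_table,
    compare_models,
    fit_geo_model,
    geo_likelihood,
)
from orodiversify.io_model import AreaCoding
from orodiversify.synthetic_data import simulate_time_tree

from oracles import brute_force_geo, random_geo_instance


class TestStateSpace:
    def test_two_areas(self):
        sp = build_state_space(("A", "B"))
        assert [set(s) for s in sp.states] == [{"A"}, {"B"}, {"A", "B"}]

    def test_counts(self):
        assert build_state_space(("A", "B", "C")).n_states == 7
        assert build_state_space(("A", "B", "C"), max_range_size=1).n_states == 3
        assert build_state_space(tuple("ABCDE"), max_range_size=2).n_states == 15

    def test_too_many_areas_rejected(self):
        with pytest.raises(ValueError):
            build_state_space(tuple("ABCDEF"))


class TestAnageneticQ:
    def test_definitional_entries(self):
        sp = build_state_space(("A", "B"))
        Q = anagenetic_Q(sp, d=0.3, e=0.1)
        iA, iAB = sp.index[frozenset("A")], sp.index[frozenset("AB")]
        assert Q[iA, iAB] == pytest.approx(0.3)
        assert Q[iAB, iA] == pytest.approx(0.1)

    def test_no_extinction_from_singletons(self):
        sp = build_state_space(("A", "B", "C"))
        Q = anagenetic_Q(sp, d=0.2, e=0.5)
        iA = sp.index[frozenset("A")]
        # only gain transitions leave a singleton
        off = [Q[iA, k] for k in range(sp.n_states) if k != iA]
        assert sum(v > 0 for v in off) == 2  # {A}->{A,B}, {A}->{A,C}

    @pytest.mark.parametrize("n_areas", [2, 3])
    def test_rows_sum_to_zero(self, n_areas):
        sp = build_state_space(tuple("ABC"[:n_areas]))
        Q = anagenetic_Q(sp, d=0.7, e=0.4)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_propagator_matches_taylor_series(self):
        sp = build_state_space(("A", "B", "C"))
        Q = anagenetic_Q(sp, d=0.3, e=0.2)
        t = 1e-4
        series = (
            np.eye(sp.n_states) + Q * t + Q @ Q * t**2 / 2 + Q @ Q @ Q * t**3 / 6
        )
        assert np.allclose(expm(Q * t), series, atol=1e-10)


class TestCladogenesis:
    def test_singleton_sympatry_only(self):
        sp = build_state_space(("A", "B"))
        table = cladogenesis_table(sp, "DEC", j=0.0)
        iA = sp.index[frozenset("A")]
        iL, iR, p = table[iA]
        assert len(p) == 1 and p[0] == pytest.approx(1.0)
        assert iL[0] == iR[0] == iA

    @pytest.mark.parametrize("family", ["DEC", "DIVALIKE"])
    @pytest.mark.parametrize("j", [0.0, 1.2])
    def test_probabilities_normalised(self, family, j):
        sp = build_state_space(("A", "B", "C"))
        table = cladogenesis_table(sp, family, j=j, plus_j=True)
        for iL, iR, p in table.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dec_plus_j_hand_enumeration(self):
        # ancestor {A}, 2 areas, j=1: sympatry weight (3-1)/3 = 2/3,
        # two jump pairs weight 1 each -> probs 1/4, 3/8, 3/8
        sp = build_state_space(("A", "B"))
        table = cladogenesis_table(sp, "DEC", j=1.0, plus_j=True)
        iA, iB = sp.index[frozenset("A")], sp.index[frozenset("B")]
        iL, iR, p = table[iA]
        outcomes = {(int(l), int(r)): float(w) for l, r, w in zip(iL, iR, p)}
        assert outcomes[(iA, iA)] == pytest.approx(1 / 4)
        assert outcomes[(iA, iB)] == pytest.approx(3 / 8)
        assert outcomes[(iB, iA)] == pytest.approx(3 / 8)

    def test_dec_widespread_uniform_at_j_zero(self):
        # classic DEC: {A,B} splits into 4 subset-sympatry + 2 vicariance
        # outcomes, all equally weighted
        sp = build_state_space(("A", "B"))
        table = cladogenesis_table(sp, "DEC", j=0.0)
        _, _, p = table[sp.index[frozenset("AB")]]
        assert len(p) == 6 and np.allclose(p, 1 / 6)

    def test_divalike_has_no_subset_sympatry(self):
        sp = build_state_space(("A", "B"))
        table = cladogenesis_table(sp, "DIVALIKE", j=0.0)
        iAB = sp.index[frozenset("AB")]
        iL, iR, p = table[iAB]
        # only the two vicariance orderings ({A},{B}) and ({B},{A})
        assert len(p) == 2
        assert iAB not in set(iL) | set(iR)

    def test_jump_requires_plus_j(self):
        sp = build_state_space(("A", "B"))
        with pytest.raises(ValueError, match="\\+J"):
            cladogenesis_table(sp, "DEC", j=0.5, plus_j=False)


class TestLikelihood:
    def test_zero_length_cherry_equals_root_prior(self, zero_cherry,
                                                  two_area_coding_same):
        sp = build_state_space(("A", "B"))
        lnl = geo_likelihood(zero_cherry, two_area_coding_same, sp,
                             GeoParams(0.1, 0.05), "DEC")
        assert lnl == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_child_swap_symmetry(self, three_tip_tree):
        sp = build_state_space(("A", "B"))
        coding = AreaCoding(("A", "B"), {"A": frozenset("A"),
                                         "B": frozenset("B"),
                                         "C": frozenset("AB")})
        params = GeoParams(0.2, 0.1)
        before = geo_likelihood(three_tip_tree, coding, sp, params, "DEC")
        for node in three_tip_tree.internal_nodes():
            node.children.reverse()
        after = geo_likelihood(three_tip_tree, coding, sp, params, "DEC")
        assert before == pytest.approx(after, abs=1e-12)

    def test_pruning_matches_enumeration_on_random_instances(self, rng):
        for _ in range(25):
            tree, coding, sp, params = random_geo_instance(rng)
            for family, plus_j in (("DEC", False), ("DEC", True),
                                   ("DIVALIKE", True)):
                p = params if plus_j else GeoParams(params.d, params.e, 0.0)
                got = geo_likelihood(tree, coding, sp, p, family, plus_j)
                want, _ = brute_force_geo(tree, coding, sp, p, family, plus_j)
                assert got == pytest.approx(want, abs=1e-8)

    def test_plus_j_at_zero_equals_base_model(self, rng):
        for _ in range(10):
            tree, coding, sp, params = random_geo_instance(rng)
            p0 = GeoParams(params.d, params.e, 0.0)
            for family in ("DEC", "DIVALIKE"):
                a = geo_likelihood(tree, coding, sp, p0, family, plus_j=True)
                b = geo_likelihood(tree, coding, sp, p0, family, plus_j=False)
                assert a == pytest.approx(b, abs=1e-9)

    def test_frozen_rates_yield_zero_one_likelihood(self, three_tip_tree):
        # with d = e = 0 and only singleton ranges modelled, sympatry is
        # the sole cladogenetic outcome: identical tips carry exactly the
        # root-prior mass, mixed tips are impossible.  (With widespread
        # ranges allowed, vicariance of a widespread root can still
        # explain mixed tips without any anagenetic event.)
        sp = build_state_space(("A", "B"), max_range_size=1)
        params = GeoParams(0.0, 0.0)
        same = AreaCoding(("A", "B"), {t: frozenset("A")
                                       for t in three_tip_tree.taxa})
        lnl = geo_likelihood(three_tip_tree, same, sp, params, "DEC")
        assert lnl == pytest.approx(np.log(1 / 2), abs=1e-9)
        mixed = AreaCoding(("A", "B"), {"A": frozenset("A"),
                                        "B": frozenset("B"),
                                        "C": frozenset("A")})
        assert geo_likelihood(three_tip_tree, mixed, sp, params, "DEC") == -np.inf

    def test_missing_tip_coding_errors(self, three_tip_tree):
        sp = build_state_space(("A", "B"))
        coding = AreaCoding(("A", "B"), {"A": frozenset("A")})
        with pytest.raises(KeyError):
            geo_likelihood(three_tip_tree, coding, sp, GeoParams(0.1, 0.1), "DEC")


class TestAncestralRanges:
    def test_zero_length_cherry_certain_ancestor(self, zero_cherry,
                                                 two_area_coding_same):
        sp = build_state_space(("A", "B"))
        marg = ancestral_ranges(zero_cherry, two_area_coding_same, sp,
                                GeoParams(0.1, 0.05), "DEC")
        assert marg["root"][sp.index[frozenset("A")]] == pytest.approx(1.0)

    def test_marginals_match_enumeration_posterior(self, rng):
        for _ in range(10):
            tree, coding, sp, params = random_geo_instance(rng, max_tips=3)
            marg = ancestral_ranges(tree, coding, sp, params, "DEC", plus_j=True)
            _, want = brute_force_geo(tree, coding, sp, params, "DEC", True)
            for nid in marg:
                assert np.allclose(marg[nid], want[nid], atol=1e-9)
                assert marg[nid].sum() == pytest.approx(1.0, abs=1e-9)


@pytest.fixture(scope="module")
def small_instance():
    tree = simulate_time_tree(12, birth_rate=0.6, seed=42)
    sp = build_state_space(("A", "B"))
    rng = np.random.default_rng(7)
    coding = AreaCoding(
        ("A", "B"),
        {t: sp.states[int(rng.integers(3))] for t in tree.taxa},
    )
    return tree, coding


class TestFitAndCompare:
    def test_plus_j_never_worse_than_nested(self, small_instance):
        tree, coding = small_instance
        base = fit_geo_model(tree, coding, "DEC", plus_j=False,
                             compute_marginals=False)
        plus = fit_geo_model(tree, coding, "DEC", plus_j=True,
                             compute_marginals=False)
        assert plus.lnL >= base.lnL - 1e-6

    def test_tip_order_invariance(self, small_instance):
        tree, coding = small_instance
        fit1 = fit_geo_model(tree, coding, "DEC", compute_marginals=False)
        permuted = AreaCoding(
            coding.areas,
            dict(sorted(coding.ranges.items(), reverse=True)),
        )
        fit2 = fit_geo_model(tree, permuted, "DEC", compute_marginals=False)
        assert fit1.lnL == pytest.approx(fit2.lnL, abs=1e-9)

    def test_aic_table_arithmetic(self, small_instance):
        tree, coding = small_instance
        base = fit_geo_model(tree, coding, "DEC", plus_j=False,
                             compute_marginals=False)
        plus = fit_geo_model(tree, coding, "DEC", plus_j=True,
                             compute_marginals=False)
        # fabricated lnL values exercise the arithmetic deterministically
        base.lnL, base.aic = -100.0, 2 * 2 - 2 * -100.0
        plus.lnL, plus.aic = -90.0, 2 * 3 - 2 * -90.0
        df = compare_models([base, plus])
        assert df["AIC"].tolist() == [186.0, 204.0]
        assert df["dAIC"].tolist() == [0.0, 18.0]
        jrow = df[df["plus_j"]].iloc[0]
        assert jrow["lrt_stat"] == pytest.approx(2 * (-90 - -100))

    def test_fits_on_different_data_rejected(self, small_instance):
        tree, coding = small_instance
        other_coding = AreaCoding(
            coding.areas,
            {t: frozenset("A") for t in tree.taxa},
        )
        a = fit_geo_model(tree, coding, "DEC", compute_marginals=False)
        b = fit_geo_model(tree, other_coding, "DEC", compute_marginals=False)
        with pytest.raises(ValueError, match="different data"):
            compare_models([a, b])
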