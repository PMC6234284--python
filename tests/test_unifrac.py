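import numpy as np
import pandas as pd
import pytest

from saltscan import SyntheticSpec, simulate_tree
from saltscan.unifrac import (
    independent_swap_null,
    lineage_groups,
    permanova,
    pooled_group_unifrac,
    rarefy,
    unweighted_unifrac,
    weighted_unifrac,
    z_test,
)

from .oracles import unifrac_oracle


class TestUniFrac:
    def test_disjoint_clades_give_one(self, four_tip_tree):
        assert unweighted_unifrac(four_tip_tree, {"A", "B"}, {"C", "D"}) == 1.0
        assert weighted_unifrac(four_tip_tree, {"A": 5}, {"C": 2}) == 1.0

    def test_identical_assemblages_give_zero(self, four_tip_tree):
        assert unweighted_unifrac(four_tip_tree, {"A", "C"}, {"A", "C"}) == 0.0
        assert weighted_unifrac(four_tip_tree, {"A": 3, "B": 1}, {"A": 3, "B": 1}) == 0.0

    def test_hand_enumerated_values(self, four_tip_tree):
        # {A,C} vs {B,D}: all four tip branches unique, both internals shared
        assert unweighted_unifrac(four_tip_tree, {"A", "C"}, {"B", "D"}) == pytest.approx(4 / 6)
        # 3:1 vs 1:3 on the AB cherry: |0.75-0.25| + |0.25-0.75| over 4
        assert weighted_unifrac(
            four_tip_tree, {"A": 3, "B": 1}, {"A": 1, "B": 3}
        ) == pytest.approx(0.25)

    def test_empty_assemblage_rejected(self, four_tip_tree):
        with pytest.raises(ValueError):
            unweighted_unifrac(four_tip_tree, set(), {"A"})
        with pytest.raises(ValueError):
            weighted_unifrac(four_tip_tree, {}, {"A": 1})

    @pytest.mark.parametrize("case", range(30))
    def test_matches_branch_enumeration_oracle(self, case):
        rng = np.random.default_rng(200 + case)
        n = int(rng.integers(4, 33))
        tree = simulate_tree(SyntheticSpec(n_taxa=n, n_transitions=0,
                                           transition_divergences=(), seed=case))
        tips = [t.name for t in tree.tips()]
        a = {t: float(c) for t, c in zip(tips, rng.integers(0, 5, n)) if c > 0}
        b = {t: float(c) for t, c in zip(tips, rng.integers(0, 5, n)) if c > 0}
        if not a or not b:
            return
        uw = unweighted_unifrac(tree, set(a), set(b))
        assert uw == pytest.approx(unifrac_oracle(tree, set(a), set(b)), abs=1e-12)
        assert 0 <= uw <= 1
        w = weighted_unifrac(tree, a, b)
        assert w == pytest.approx(unifrac_oracle(tree, a, b, weighted=True), abs=1e-12)
        assert 0 <= w <= 1

    def test_cross_check_against_scikit_bio(self, four_tip_tree):
        from skbio.diversity.beta import unweighted_unifrac as sk_uw
        from skbio.diversity.beta import weighted_unifrac as sk_w

        taxa = list("ABCD")
        assert unweighted_unifrac(four_tip_tree, {"A", "C"}, {"B", "D"}) == pytest.approx(
            sk_uw([1, 0, 1, 0], [0, 1, 0, 1], taxa=taxa, tree=four_tip_tree)
        )
        assert weighted_unifrac(four_tip_tree, {"A": 3, "B": 1}, {"A": 1, "B": 3}) == pytest.approx(
            sk_w([3, 1, 0, 0], [1, 3, 0, 0], taxa=taxa, tree=four_tip_tree, normalized=True)
        )


class TestPooledGroupUniFrac:
    def test_disjoint_and_fully_shared_families(self, small_community):
        com = small_community
        lineage = pd.Series(
            {t: ("pA;cA;oA;fA;gA" if h == "marine" else "pA;cA;oA;fA;gB")
             for t, h in com.truth.habitats.items()}
        )
        # family fA spans both habitats; construct one where habitats are
        # disjoint subtrees by using the habitat partition itself per phylum
        table = pooled_group_unifrac(com.tree, com.counts, com.metadata, lineage, rank=1)
        assert set(table.index) == {"pA"}
        assert 0 <= table.loc["pA", "pooled_unifrac"] <= 1

    def test_everything_shared_gives_zero(self, four_tip_tree, toy_counts):
        counts = pd.DataFrame(
            {"M01": [1, 1], "F01": [1, 1]}, index=["A", "C"]
        )
        metadata = pd.DataFrame(
            {"sample_id": ["M01", "F01"], "habitat": ["marine", "freshwater"],
             "site": ["m", "f"], "depth_class": ["surface"] * 2}
        )
        lineage = pd.Series({"A": "p1;c;o;f;g", "C": "p1;c;o;f;g"})
        table = pooled_group_unifrac(four_tip_tree, counts, metadata, lineage, rank=1)
        assert table.loc["p1", "pooled_unifrac"] == 0.0

    def test_group_absent_from_one_habitat_flagged(self, four_tip_tree):
        counts = pd.DataFrame({"M01": [1, 1], "F01": [0, 0]}, index=["A", "C"])
        metadata = pd.DataFrame(
            {"sample_id": ["M01", "F01"], "habitat": ["marine", "freshwater"],
             "site": ["m", "f"], "depth_class": ["surface"] * 2}
        )
        lineage = pd.Series({"A": "p1;c;o;f;g", "C": "p1;c;o;f;g"})
        table = pooled_group_unifrac(four_tip_tree, counts, metadata, lineage, rank=1)
        assert not table.loc["p1", "evaluable"]
        assert np.isnan(table.loc["p1", "pooled_unifrac"])


class TestRarefy:
    def test_columns_sum_to_depth_and_shallow_dropped(self):
        counts = pd.DataFrame({"deep": [50, 30, 20], "shallow": [3, 1, 0]},
                              index=list("abc"))
        with pytest.warns(UserWarning):
            rare = rarefy(counts, depth=10, seed=1)
        assert list(rare.columns) == ["deep"]
        assert rare["deep"].sum() == 10

    def test_depth_equal_to_total_keeps_column(self):
        counts = pd.DataFrame({"s": [4, 6]}, index=["a", "b"])
        rare = rarefy(counts, depth=10, seed=0)
        assert rare["s"].tolist() == [4, 6]

    def test_hypergeometric_expectation(self):
        # mean rarefied count over many seeds approaches depth * share
        counts = pd.DataFrame({"s": [70, 20, 10]}, index=list("abc"))
        depth = 40
        draws = np.stack([rarefy(counts, depth, seed=s)["s"].to_numpy() for s in range(1000)])
        expected = depth * np.array([0.7, 0.2, 0.1])
        # hypergeometric variance n*p*(1-p)*(N-n)/(N-1)
        var = depth * expected / depth * (1 - expected / depth) * (100 - depth) / 99
        se = np.sqrt(var / 1000)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-9)

    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError):
            rarefy(pd.DataFrame({"s": [1]}), depth=0)


class TestSwapNull:
    def test_margins_preserved_on_every_draw(self):
        rng = np.random.default_rng(4)
        mat = (rng.random((12, 8)) < 0.4).astype(int)
        draws = independent_swap_null(mat, n_rand=200, seed=0)
        assert draws.shape == (200, 12, 8)
        assert (draws.sum(axis=1) == mat.sum(axis=0)).all()
        assert (draws.sum(axis=2) == mat.sum(axis=1)).all()
        # the chain actually moves
        assert len({d.tobytes() for d in draws}) > 1

    def test_two_by_two_checkerboard_reachable_states(self):
        mat = np.array([[1, 0], [0, 1]])
        draws = independent_swap_null(mat, n_rand=100, seed=3)
        states = {d.tobytes() for d in draws}
        assert states <= {np.array([[1, 0], [0, 1]], dtype=np.int8).tobytes(),
                          np.array([[0, 1], [1, 0]], dtype=np.int8).tobytes()}
        assert len(states) == 2

    def test_unswappable_matrix_returned_with_warning(self):
        mat = np.ones((3, 3), dtype=int)
        with pytest.warns(UserWarning):
            draws = independent_swap_null(mat, n_rand=5, seed=0)
        assert (draws == 1).all()

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            independent_swap_null(np.array([[2, 0], [0, 1]]), 10)


class TestZTest:
    def test_hand_values(self):
        null = np.array([0.4, 0.6, 0.5, 0.5])  # mean 0.5, sd ~0.0816
        z, p, _ = z_test(0.9, null)
        assert z == pytest.approx((0.9 - 0.5) / np.std(null, ddof=1))
        z0, p0, _ = z_test(0.5, null)
        assert z0 == 0.0
        assert p0 == pytest.approx(0.5)

    def test_bonferroni_multiplies_and_caps(self):
        null = np.random.default_rng(0).normal(0.5, 0.1, 100)
        _, p, p20 = z_test(null.mean() + 0.233, null, n_groups=20)
        assert p20 == pytest.approx(min(1.0, p * 20))

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            z_test(1.0, [0.5, 0.5, 0.5])


class TestPermanova:
    def test_four_point_hand_computation(self):
        # two tight pairs: d within pairs 1, across pairs 2
        # SS_total = (1+1+4+4+4+4)/4 = 4.5; SS_within = 0.5+0.5 = 1
        # F = (3.5/1)/(1/2) = 7; R2 = 3.5/4.5
        mat = np.array(
            [[0, 1, 2, 2], [1, 0, 2, 2], [2, 2, 0, 1], [2, 2, 1, 0]], dtype=float
        )
        f, r2, p = permanova(mat, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert f == pytest.approx(7.0)
        assert r2 == pytest.approx(3.5 / 4.5)
        assert 0 < p <= 1

    def test_perfect_separation(self):
        # zero within-group distance, positive between: R2 = 1, F = inf, and
        # no mixing permutation can match, so p attains its minimum for any
        # permutation not reproducing the partition
        n = 12
        mat = np.zeros((n, n))
        mat[:6, 6:] = 1.0
        mat[6:, :6] = 1.0
        labels = ["a"] * 6 + ["b"] * 6
        f, r2, p = permanova(mat, labels, n_perm=99, seed=2)
        assert r2 == pytest.approx(1.0)
        assert np.isinf(f)
        assert p == pytest.approx(1 / 100)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            permanova(np.zeros((4, 4)), ["a"] * 4)


def test_lineage_groups_rank_errors():
    lineage = pd.Series({"t1": "p1;c1", "t2": "p1;c2"})
    assert set(lineage_groups(lineage, 2)) == {"p1;c1", "p1;c2"}
    with pytest.raises(ValueError):
        lineage_groups(lineage, 3)
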