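import numpy as np
import pandas as pd
import pytest

from saltscan.sharing import (
    accumulation_curve,
    filter_groups,
    find_shared_taxa,
    fold_enrichment,
)


def test_shared_taxa_basic_rules(toy_counts):
    counts, metadata = toy_counts
    report = find_shared_taxa(counts, metadata)
    # t1 marine-only, t2 freshwater-only, t4 marine-only; t3 in both
    assert report.shared_taxa == ["t3"]
    row = report.per_group.loc["all"]
    assert row["n_shared"] == 1
    assert row["n_marine_total"] == 3
    assert row["n_freshwater_total"] == 2


def test_single_count_in_each_habitat_is_shared():
    counts = pd.DataFrame({"M01": [1], "F01": [1]}, index=["t"])
    metadata = pd.DataFrame(
        {"sample_id": ["M01", "F01"], "habitat": ["marine", "freshwater"],
         "site": ["a", "b"], "depth_class": ["surface"] * 2}
    )
    assert find_shared_taxa(counts, metadata).shared_taxa == ["t"]


def test_missing_metadata_sample_errors(toy_counts):
    counts, metadata = toy_counts
    with pytest.raises(KeyError):
        find_shared_taxa(counts, metadata[metadata.sample_id != "F02"])


def test_shared_report_matches_generator_truth(small_community):
    com = small_community
    report = find_shared_taxa(com.counts, com.metadata, com.lineage, rank=1)
    assert sorted(report.shared_taxa) == sorted(com.truth.expected_shared_taxa)


def test_shared_invariant_to_column_order(small_community):
    com = small_community
    shuffled = com.counts[list(reversed(com.counts.columns))]
    a = find_shared_taxa(com.counts, com.metadata).shared_taxa
    b = find_shared_taxa(shuffled, com.metadata).shared_taxa
    assert a == b


class TestFilterGroups:
    @staticmethod
    def table(n_fresh_samples):
        taxa = [f"t{i}" for i in range(5)]
        samples = {f"M{i}": [500] * 5 for i in range(3)}
        samples.update({f"F{i}": [500] * 5 for i in range(n_fresh_samples)})
        counts = pd.DataFrame(samples, index=taxa)
        metadata = pd.DataFrame(
            {
                "sample_id": list(samples),
                "habitat": ["marine" if s.startswith("M") else "freshwater" for s in samples],
                "site": list(samples),
                "depth_class": ["surface"] * len(samples),
            }
        )
        lineage = pd.Series({t: "p1;c;o;f;g" for t in taxa})
        return counts, metadata, lineage

    def test_group_in_two_freshwater_samples_dropped(self):
        counts, metadata, lineage = self.table(2)
        retained, _ = filter_groups(counts, lineage, metadata, rank=1)
        assert retained == []

    def test_full_group_retained(self):
        counts, metadata, lineage = self.table(3)
        retained, _ = filter_groups(counts, lineage, metadata, rank=1)
        assert retained == ["p1"]

    def test_sample_below_500_excluded_for_that_group_only(self):
        counts, metadata, lineage = self.table(3)
        counts.loc[:, "F0"] = [499, 0, 0, 0, 0]
        retained, included = filter_groups(counts, lineage, metadata, rank=1)
        assert "F0" not in included["p1"]
        assert retained == []  # only 2 qualifying freshwater samples remain


class TestAccumulation:
    @staticmethod
    def fixture():
        # F1={a,b}, F2={b,c}; marine pool={b,c,d}
        counts = pd.DataFrame(
            {
                "F1": [1, 1, 0, 0],
                "F2": [0, 1, 1, 0],
                "M1": [0, 1, 1, 1],
            },
            index=list("abcd"),
        )
        metadata = pd.DataFrame(
            {
                "sample_id": ["F1", "F2", "M1"],
                "habitat": ["freshwater", "freshwater", "marine"],
                "site": ["f1", "f2", "m1"],
                "depth_class": ["surface"] * 3,
            }
        )
        return counts, metadata

    def test_two_site_enumeration(self):
        counts, metadata = self.fixture()
        # order F1 first: shared counts (1, 2); order F2 first: (2, 2)
        curve = accumulation_curve(counts, metadata, axis_habitat="freshwater",
                                   n_orderings=200, seed=0)
        assert curve.mean_shared[0] == pytest.approx(1.5, abs=0.15)
        assert curve.mean_shared[1] == pytest.approx(2.0)
        assert curve.min_shared[0] == 1 and curve.max_shared[0] == 2

    def test_single_axis_site(self):
        counts, metadata = self.fixture()
        curve = accumulation_curve(counts, metadata, axis_habitat="marine",
                                   n_orderings=5, seed=1)
        assert curve.n_sites.tolist() == [1]
        assert curve.mean_shared[0] == 2  # {b,c} shared with the fresh pool

    def test_mean_curve_non_decreasing_and_endpoint_consistent(self, small_community):
        com = small_community
        curve = accumulation_curve(com.counts, com.metadata, axis_habitat="freshwater",
                                   n_orderings=50, seed=3)
        assert np.all(np.diff(curve.mean_shared) >= -1e-9)
        report = find_shared_taxa(com.counts, com.metadata)
        assert curve.mean_shared[-1] == report.n_shared

    def test_bad_orderings_rejected(self):
        counts, metadata = self.fixture()
        with pytest.raises(ValueError):
            accumulation_curve(counts, metadata, n_orderings=0)


class TestFoldEnrichment:
    @staticmethod
    def build(m_vals, f_vals):
        counts = pd.DataFrame(
            {"M01": m_vals, "F01": f_vals}, index=[f"t{i}" for i in range(len(m_vals))]
        )
        metadata = pd.DataFrame(
            {"sample_id": ["M01", "F01"], "habitat": ["marine", "freshwater"],
             "site": ["a", "b"], "depth_class": ["surface"] * 2}
        )
        lineage = pd.Series({t: f"p{t};c;o;f;g" for t in counts.index})
        return counts, metadata, lineage

    def test_tenfold_enrichment_is_one(self):
        # group t0: 2% of freshwater reads vs 0.2% of marine reads
        counts, metadata, lineage = self.build([2, 998], [20, 980])
        table = fold_enrichment(counts, lineage, metadata, rank=1)
        assert table.loc["pt0", "log10_fold_change"] == pytest.approx(1.0)

    def test_equal_medians_give_zero(self):
        counts, metadata, lineage = self.build([10, 90], [10, 90])
        table = fold_enrichment(counts, lineage, metadata, rank=1)
        assert table["log10_fold_change"].tolist() == [0.0, 0.0]

    def test_antisymmetric_under_habitat_swap(self, small_community):
        com = small_community
        table = fold_enrichment(com.counts, com.lineage, com.metadata, rank=1)
        swapped_meta = com.metadata.copy()
        swapped_meta["habitat"] = swapped_meta["habitat"].map(
            {"marine": "freshwater", "freshwater": "marine"}
        )
        swapped = fold_enrichment(com.counts, com.lineage, swapped_meta, rank=1)
        keep = ~(table["pseudo_abundance_used"] | swapped["pseudo_abundance_used"])
        assert np.allclose(
            table.loc[keep, "log10_fold_change"],
            -swapped.loc[keep, "log10_fold_change"],
        )
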