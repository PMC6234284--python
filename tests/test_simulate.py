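import numpy as np
import pytest

from saltscan import (
    SyntheticSpec,
    assign_habitats,
    evolve_sequences,
    sample_counts,
    simulate_community,
    simulate_tree,
)
from saltscan.simulate import jc_expected_hamming, realized_transition_divergences


def spec_of(**kw):
    base = dict(n_taxa=30, n_transitions=0, transition_divergences=(), seed=1)
    base.update(kw)
    return SyntheticSpec(**base)


class TestSpecValidation:
    def test_divergence_count_must_match(self):
        with pytest.raises(ValueError):
            spec_of(n_transitions=2, transition_divergences=(0.1,))

    def test_divergences_bounded(self):
        with pytest.raises(ValueError):
            spec_of(n_transitions=1, transition_divergences=(1.5,))

    def test_library_sizes_positive(self):
        with pytest.raises(ValueError):
            spec_of(library_size_range=(0, 10))


class TestSimulateTree:
    def test_smallest_tree(self):
        tree = simulate_tree(spec_of(n_taxa=2))
        assert tree.count(tips=True) == 2
        assert sum(1 for n in tree.traverse() if not n.is_tip()) == 1

    def test_rejects_single_taxon(self):
        with pytest.raises(ValueError):
            simulate_tree(spec_of(n_taxa=1))

    def test_deterministic_newick(self):
        s = spec_of(n_taxa=50, seed=1)
        assert str(simulate_tree(s)) == str(simulate_tree(s))

    def test_structure_and_positive_lengths(self):
        tree = simulate_tree(spec_of(n_taxa=100, seed=7))
        assert tree.count(tips=True) == 100
        lengths = [n.length for n in tree.traverse() if n.parent is not None]
        assert all(b > 0 for b in lengths)
        assert sum(lengths) > 0


class TestAssignHabitats:
    def test_no_transitions_single_habitat(self):
        spec = spec_of(immigrant_weight=0.0)
        tree = simulate_tree(spec)
        truth = assign_habitats(tree, spec)
        assert set(truth.habitats.values()) == {"marine"}
        assert truth.events == []
        with pytest.warns(UserWarning):
            counts = sample_counts(truth, spec)
        assert truth.expected_shared_taxa == []

    def test_zero_divergence_forces_identical_sequences(self):
        spec = spec_of(n_transitions=1, transition_divergences=(0.0,), seed=5)
        com = simulate_community(spec)
        event = com.truth.events[0]
        assert event["realized_divergence"] == 0.0
        a = com.seqs.sequences[com.seqs.ids.index(event["focal_flipped"])]
        b = com.seqs.sequences[com.seqs.ids.index(event["focal_ancestral"])]
        assert a == b

    def test_two_event_divergences_recovered_exhaustively(self):
        spec = spec_of(n_taxa=40, n_transitions=2,
                       transition_divergences=(0.01, 0.20), seed=3)
        com = simulate_community(spec)
        tol = 2 / spec.alignment_length
        realized = sorted(e["realized_divergence"] for e in com.truth.events)
        assert abs(realized[0] - 0.01) <= tol
        assert abs(realized[1] - 0.20) <= tol

    def test_truth_matches_exhaustive_recomputation(self, small_community):
        com = small_community
        recomputed = realized_transition_divergences(com.truth, com.seqs)
        assert recomputed == [e["realized_divergence"] for e in com.truth.events]

    def test_infeasible_divergence_rejected(self):
        spec = spec_of(n_transitions=1, transition_divergences=(0.001,),
                       alignment_length=290)
        tree = simulate_tree(spec)
        with pytest.raises(ValueError, match="resolution"):
            assign_habitats(tree, spec)


class TestEvolveSequences:
    def test_zero_branch_lengths_identical_sequences(self):
        spec = spec_of(n_taxa=5)
        tree = simulate_tree(spec)
        for node in tree.traverse():
            if node.parent is not None:
                node.length = 0.0
        seqs = evolve_sequences(tree, spec)
        assert len(set(seqs.sequences)) == 1

    def test_saturation_matches_jukes_cantor_expectation(self):
        # two tips at 0.5 expected substitutions/site: observed mismatch
        # fraction within 3 binomial SE of 0.75(1 - e^(-4*0.5/3)) ~ 0.3656
        spec = spec_of(n_taxa=2, alignment_length=10_000, seed=13,
                       baseline_divergence=0.5)
        tree = simulate_tree(spec)
        seqs = evolve_sequences(tree, spec)
        mismatch = np.mean(
            [a != b for a, b in zip(seqs.sequences[0], seqs.sequences[1])]
        )
        expected = jc_expected_hamming(0.5)
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(mismatch - expected) < 3 * se

    def test_deterministic_fasta_bytes(self, tmp_path):
        spec = spec_of(n_taxa=20, n_transitions=1, transition_divergences=(0.1,), seed=2)
        paths = []
        for name in ("a.fasta", "b.fasta"):
            tree = simulate_tree(spec)
            assign_habitats(tree, spec)
            seqs = evolve_sequences(tree, spec)
            p = tmp_path / name
            seqs.to_fasta(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestSampleCounts:
    def test_fixed_library_size_column_sums(self):
        spec = spec_of(library_size_range=(100, 100))
        tree = simulate_tree(spec)
        truth = assign_habitats(tree, spec)
        counts = sample_counts(truth, spec)
        assert (counts.sum(axis=0) == 100).all()

    def test_column_sums_within_drawn_range(self, small_community):
        lo, hi = small_community.spec.library_size_range
        sums = small_community.counts.sum(axis=0)
        assert ((sums >= lo) & (sums <= hi)).all()

    def test_zero_immigrant_weight_keeps_habitats_pure(self):
        spec = spec_of(n_transitions=1, transition_divergences=(0.1,),
                       immigrant_weight=0.0, seed=9)
        com = simulate_community(spec)
        fresh = [t for t, h in com.truth.habitats.items() if h == "freshwater"]
        marine_cols = [c for c in com.counts.columns if c.startswith("M")]
        fresh_cols = [c for c in com.counts.columns if c.startswith("F")]
        assert com.counts.loc[fresh, marine_cols].to_numpy().sum() == 0
        marine = [t for t, h in com.truth.habitats.items() if h == "marine"]
        assert com.counts.loc[marine, fresh_cols].to_numpy().sum() == 0
        assert com.truth.expected_shared_taxa == []

    def test_rare_fraction_puts_taxa_near_detection_limit(self):
        spec = spec_of(n_taxa=100, rare_fraction=0.4, seed=21,
                       library_size_range=(10_000, 10_000))
        com = simulate_community(spec)
        marine_cols = [c for c in com.counts.columns if c.startswith("M")]
        mean_counts = com.counts[marine_cols].mean(axis=1)
        marine = [t for t, h in com.truth.habitats.items() if h == "marine"]
        near_limit = (mean_counts.loc[marine] < 2).sum()
        assert near_limit >= 0.3 * len(marine)

    def test_determinism_across_runs(self):
        spec = spec_of(n_taxa=50, rare_fraction=0.5, seed=11,
                       library_size_range=(10_000, 10_000))
        a = simulate_community(spec).counts
        b = simulate_community(spec).counts
        assert a.equals(b)
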