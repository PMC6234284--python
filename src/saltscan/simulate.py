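"""Synthetic marine-freshwater communities with a controllable transition history.

The generator produces everything the downstream analyses consume: a rooted
ultrametric phylogeny (pure-birth), habitat labels with a chosen number of
marine-to-freshwater clade transitions at requested sequence divergences,
aligned sequences evolved under an equal-rates 4-state (Jukes-Cantor-like)
model, and taxon x sample count tables with log-normal abundances, uneven
library sizes and many near-detection-limit taxa.

Each transition event flips the habitat of a clade and controls the nearest
cross-habitat sequence distance exactly: the clade's ancestral sequence is
re-derived from the realized sequence of a designated ancestral-habitat
focal tip with exactly round(d * L) substitutions at distinct sites, the
nearest clade tip keeps that sequence verbatim, and the rest of the clade
radiates shallowly from it.  Plain stochastic site evolution would scatter
the realized distance by a binomial standard deviation of ~sqrt(d(1-d)/L)
(several sites at L = 290); the imposition pins it to within half a site.
So that the focal pair is also the pair complete-linkage clustering joins
first, the tree is locally rescaled for isolation: the focal ancestral tip's
pendant branch is extended and the clade's stem set so no third sequence is
expected within a safety margin of the requested divergence.

All randomness flows from one integer seed; identical specs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from saltscan.seqdist import AlignedSequenceSet

# fixed per-stage stream tags so the four operations are independently
# deterministic under one spec seed
_TREE, _HABITAT, _SEQ, _COUNT = 11, 23, 37, 53

# transition-clade geometry (expected substitutions/site): clades radiate
# shallowly around their imposed ancestral sequence, and no third sequence is
# expected within this hamming margin of a focal pair
_CLADE_DEPTH = 5e-4
_ISOLATION_MARGIN = 0.05

_BASES = "ACGT"


def jc_expected_hamming(path_length: float) -> float:
    """Expected fraction of mismatched sites between tips at a given path length."""
    return 0.75 * (1.0 - np.exp(-4.0 * path_length / 3.0))


def jc_path_for_hamming(d: float) -> float:
    """Substitutions/site giving an expected mismatch fraction d (d < 0.75)."""
    if d >= 0.75:
        raise ValueError("mismatch fractions >= 0.75 are unreachable under JC")
    return -0.75 * np.log(1.0 - 4.0 * d / 3.0)


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic community generator.

    ``transition_divergences`` are fractional sequence distances (mismatch
    fractions) requested for the nearest cross-habitat tip pair of each
    transition event.  ``rare_fraction`` is the fraction of taxa whose
    expected per-sample count is below one read, emulating populations at
    the detection limit.  ``immigrant_weight`` multiplies the relative
    abundance of taxa sampled outside their home habitat; 0 disables
    sporadic cross-habitat immigration.
    """

    n_taxa: int
    alignment_length: int = 290
    n_transitions: int = 1
    transition_divergences: tuple[float, ...] = (0.04,)
    n_marine_samples: int = 8
    n_freshwater_samples: int = 8
    library_size_range: tuple[int, int] = (5000, 15000)
    abundance_lognormal_mu_sigma: tuple[float, float] = (0.0, 1.5)
    rare_fraction: float = 0.3
    immigrant_weight: float = 1e-3
    baseline_divergence: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be positive")
        if self.n_transitions < 0:
            raise ValueError("n_transitions must be non-negative")
        self.transition_divergences = tuple(self.transition_divergences)
        if len(self.transition_divergences) != self.n_transitions:
            raise ValueError("need one transition divergence per transition")
        if any(not 0.0 <= d <= 1.0 for d in self.transition_divergences):
            raise ValueError("transition divergences must lie in [0, 1]")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError("library sizes must be >= 1 with lo <= hi")
        if not 0.0 <= self.rare_fraction < 1.0:
            raise ValueError("rare_fraction must lie in [0, 1)")
        if self.immigrant_weight < 0:
            raise ValueError("immigrant_weight must be >= 0")
        if self.n_marine_samples < 1 or self.n_freshwater_samples < 1:
            raise ValueError("need at least one sample per habitat")

    def to_dict(self) -> dict:
        return {
            "n_taxa": self.n_taxa,
            "alignment_length": self.alignment_length,
            "n_transitions": self.n_transitions,
            "transition_divergences": list(self.transition_divergences),
            "n_marine_samples": self.n_marine_samples,
            "n_freshwater_samples": self.n_freshwater_samples,
            "library_size_range": list(self.library_size_range),
            "abundance_lognormal_mu_sigma": list(self.abundance_lognormal_mu_sigma),
            "rare_fraction": self.rare_fraction,
            "immigrant_weight": self.immigrant_weight,
            "baseline_divergence": self.baseline_divergence,
            "seed": self.seed,
        }


@dataclass
class SyntheticTruth:
    """Ground truth for parameter-recovery checks."""

    taxa: list[str]
    habitats: dict[str, str]
    events: list[dict]
    expected_shared_taxa: list[str] | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "taxa": self.taxa,
                    "habitats": self.habitats,
                    "events": self.events,
                    "expected_shared_taxa": self.expected_shared_taxa,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def simulate_tree(spec: SyntheticSpec) -> TreeNode:
    """Rooted ultrametric pure-birth (Yule) tree with ``n_taxa`` tips.

    Branch lengths are scaled so the mean tip-to-tip path length equals
    ``baseline_divergence`` expected substitutions per site.
    """
    if spec.n_taxa < 2:
        raise ValueError("a tree needs at least 2 taxa")
    rng = np.random.default_rng([_TREE, spec.seed])
    root = TreeNode()
    first = [TreeNode(), TreeNode()]
    root.extend(first)
    birth = {id(first[0]): 0.0, id(first[1]): 0.0}
    tips = list(first)
    t = 0.0
    while len(tips) < spec.n_taxa:
        t += rng.exponential(1.0 / len(tips))
        idx = int(rng.integers(len(tips)))
        node = tips[idx]
        node.length = t - birth[id(node)]
        children = [TreeNode(), TreeNode()]
        node.extend(children)
        birth[id(children[0])] = birth[id(children[1])] = t
        tips[idx] = children[0]
        tips.append(children[1])
    t_end = t + rng.exponential(1.0 / len(tips))
    for node in tips:
        node.length = t_end - birth[id(node)]
    # scale to the requested mean pairwise divergence
    n = spec.n_taxa
    total_pairs = n * (n - 1) / 2
    weighted = 0.0
    for node in root.postorder(include_self=False):
        below = node.count(tips=True) or 1
        weighted += (node.length or 0.0) * below * (n - below)
    factor = spec.baseline_divergence * total_pairs / weighted
    for node in root.postorder(include_self=False):
        node.length = (node.length or 0.0) * factor
    # deterministic names: tips left-to-right, internals preorder
    for i, tip in enumerate(root.tips()):
        tip.name = f"T{i + 1:04d}"
    k = 0
    for node in root.preorder(include_self=True):
        if not node.is_tip():
            k += 1
            node.name = f"N{k:04d}"
    return root


def _subtree_tip_names(node: TreeNode) -> list[str]:
    return [t.name for t in node.tips()]


def assign_habitats(
    tree: TreeNode,
    spec: SyntheticSpec,
    transition_nodes: list[str] | None = None,
) -> SyntheticTruth:
    """Assign habitats: marine root state plus ``n_transitions`` clade flips.

    Each chosen internal node's subtree flips to freshwater; the tree is
    locally rescaled so the nearest cross-habitat tip pair approaches the
    requested divergence (the sequence stage then pins it exactly).  Chosen
    subtrees are disjoint and leave both habitats non-empty.  The event list
    is annotated onto the tree for the sequence stage.
    """
    rng = np.random.default_rng([_HABITAT, spec.seed])
    L = spec.alignment_length
    for d in spec.transition_divergences:
        if d > 0.70:
            raise ValueError(
                f"transition divergence {d} infeasible: equal-rates substitution "
                "saturates at 0.75 observed distance"
            )
        if 0.0 < d < 0.5 / L:
            raise ValueError(
                f"transition divergence {d} below the resolution of a "
                f"{L}-position alignment (minimum nonzero distance 1/{L})"
            )
    tips = [t.name for t in tree.tips()]
    habitats = {t: "marine" for t in tips}
    internals = [n for n in tree.preorder(include_self=False) if not n.is_tip()]
    if spec.n_transitions > len(internals):
        raise ValueError("more transitions requested than internal nodes")

    if transition_nodes is not None:
        by_name = {n.name: n for n in internals}
        chosen = [by_name[name] for name in transition_nodes]
    else:
        max_clade = max(1, len(tips) // 3)
        # children of the root are excluded so the top-level clade (the
        # derived phylum) always keeps ancestral-habitat members
        candidates = [
            n for n in internals
            if n.parent is not tree and n.count(tips=True) <= max_clade
        ]
        order = rng.permutation(len(candidates))
        chosen = []
        taken: set[str] = set()
        for idx in order:
            if len(chosen) == spec.n_transitions:
                break
            node = candidates[idx]
            names = set(_subtree_tip_names(node))
            if names & taken:
                continue
            chosen.append(node)
            taken |= names
        if len(chosen) < spec.n_transitions:
            raise ValueError("could not place disjoint transition clades; lower n_transitions")

    flipped: set[str] = set()
    for node in chosen:
        for name in _subtree_tip_names(node):
            habitats[name] = "freshwater" if habitats[name] == "marine" else "marine"
            flipped.add(name)
    if spec.n_transitions and len(flipped) == len(tips):
        raise ValueError("transitions flipped every tip; both habitats must remain")

    events: list[dict] = []
    tip_nodes = {t.name: t for t in tree.tips()}
    for node, d in zip(chosen, spec.transition_divergences):
        inside = _subtree_tip_names(node)
        inside_set = set(inside)
        inside_habitat = habitats[inside[0]]
        outside_opp = [t for t in tips if t not in inside_set and habitats[t] != inside_habitat]
        if not outside_opp:
            raise ValueError("no opposite-habitat tip outside a transition clade")
        # isolation margin: no third sequence expected within d + margin of the
        # focal pair, so the pair is the first cross-habitat join in clustering
        t_margin = jc_path_for_hamming(min(d + _ISOLATION_MARGIN, 0.70))
        parent = node.parent
        # prefer a focal ancestral tip within the same top-level clade (the
        # phylum in the derived lineage), so per-phylum scans see the pair
        anc1 = node
        while anc1.parent is not None and anc1.parent.parent is not None:
            anc1 = anc1.parent
        same_phylum = set(_subtree_tip_names(anc1)) - inside_set
        pool = [t for t in outside_opp if t in same_phylum] or outside_opp
        b, focal_out = min((parent.distance(tip_nodes[t]), t) for t in pool)
        # extend the focal ancestral tip's pendant so no outside tip sits
        # closer to it than the margin
        others = [t for t in tips if t not in inside_set and t != focal_out]
        if others:
            fo = tip_nodes[focal_out]
            nearest = min(fo.distance(tip_nodes[t]) for t in others)
            if nearest < t_margin:
                fo.length = (fo.length or 0.0) + (t_margin - nearest)
        # shrink the clade to a shallow radiation around its imposed ancestor
        depths = [node.distance(tip_nodes[t]) for t in inside]
        max_depth = max(depths)
        if max_depth > 0:
            alpha = _CLADE_DEPTH / max_depth
            for desc in node.postorder(include_self=False):
                desc.length = (desc.length or 0.0) * alpha
        # stem: keep every cross-habitat tree path at or beyond the margin
        b_min = min(parent.distance(tip_nodes[t]) for t in outside_opp)
        node.length = max(1e-6, t_margin - b_min)
        focal_in = min(zip(depths, inside))[1]
        events.append(
            {
                "node": node.name,
                "requested_divergence": float(d),
                "focal_flipped": focal_in,
                "focal_ancestral": focal_out,
                "subtree_tips": inside,
                "realized_divergence": None,
            }
        )
    tree.transition_events = events
    return SyntheticTruth(taxa=tips, habitats=habitats, events=events)


def evolve_sequences(tree: TreeNode, spec: SyntheticSpec) -> AlignedSequenceSet:
    """Evolve one sequence per tip under an equal-rates 4-state model.

    Each site mutates independently on each branch with the exact
    Jukes-Cantor substitution probability 3/4 (1 - e^(-4 b / 3)) and lands
    uniformly on one of the three other bases.  For each transition event
    annotated on the tree, the clade's ancestral sequence is then replaced
    by a copy of the focal ancestral tip's realized sequence carrying
    exactly round(d * L) substitutions at distinct sites, the clade is
    re-evolved from it, and the focal flipped tip keeps the imposed
    sequence verbatim — pinning the nearest cross-habitat distance.
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("need at least 2 tips")
    L = spec.alignment_length
    if L < 1:
        raise ValueError("alignment_length must be >= 1")
    rng = np.random.default_rng([_SEQ, spec.seed])
    seqs: dict[int, np.ndarray] = {}
    root = tree

    def evolve_below(start: TreeNode) -> None:
        for node in start.preorder(include_self=False):
            parent_seq = seqs[id(node.parent)]
            b = node.length or 0.0
            p = jc_expected_hamming(b)  # exact JC per-site substitution probability
            seq = parent_seq.copy()
            mask = rng.random(L) < p
            n_mut = int(mask.sum())
            if n_mut:
                seq[mask] = (seq[mask] + rng.integers(1, 4, size=n_mut, dtype=np.int8)) % 4
            seqs[id(node)] = seq

    seqs[id(root)] = rng.integers(0, 4, size=L, dtype=np.int8)
    evolve_below(root)
    by_id_name = {n.name: n for n in root.traverse(include_self=True)}
    for event in getattr(tree, "transition_events", []):
        d = event["requested_divergence"]
        m = int(round(d * L))
        node = by_id_name[event["node"]]
        focal_out = by_id_name[event["focal_ancestral"]]
        imposed = seqs[id(focal_out)].copy()
        if m:
            sites = rng.choice(L, size=m, replace=False)
            imposed[sites] = (imposed[sites] + rng.integers(1, 4, size=m, dtype=np.int8)) % 4
        seqs[id(node)] = imposed
        evolve_below(node)
        seqs[id(by_id_name[event["focal_flipped"]])] = imposed
    by_name = {t.name: seqs[id(t)] for t in tips}
    ids = [t.name for t in tips]
    sequences = ["".join(_BASES[c] for c in by_name[t]) for t in ids]
    return AlignedSequenceSet(ids=ids, sequences=sequences)


def realized_transition_divergences(
    truth: SyntheticTruth, seqs: AlignedSequenceSet
) -> list[float]:
    """Fill each event's realized divergence from the evolved sequences.

    Realized value = minimum raw mismatch fraction between any tip of the
    flipped clade and any opposite-habitat tip, by exhaustive comparison.
    """
    mat = seqs.matrix
    index = {sid: i for i, sid in enumerate(seqs.ids)}
    out = []
    for event in truth.events:
        inside = event["subtree_tips"]
        inside_habitat = truth.habitats[inside[0]]
        outside = [
            t for t in truth.taxa
            if t not in set(inside) and truth.habitats[t] != inside_habitat
        ]
        best = 1.0
        for i in inside:
            for o in outside:
                frac = np.count_nonzero(mat[index[i]] != mat[index[o]]) / mat.shape[1]
                best = min(best, frac)
        event["realized_divergence"] = float(best)
        out.append(float(best))
    return out


def assign_lineage(tree: TreeNode) -> pd.Series:
    """Derive a 5-rank lineage string per tip from its ancestor nodes.

    Rank r (1=phylum .. 5=genus) takes the name of the ancestor r steps below
    the root along the tip's path (reusing the deepest available ancestor for
    shallow tips), so labels form a proper hierarchy.
    """
    prefixes = ["p", "c", "o", "f", "g"]
    records = {}
    for tip in tree.tips():
        path = [a for a in reversed(list(tip.ancestors()))]  # root .. parent
        path = path + [tip]
        labels = []
        for r in range(1, 6):
            node = path[min(r, len(path) - 1)]
            labels.append(f"{prefixes[r - 1]}{node.name}")
        records[tip.name] = ";".join(labels)
    return pd.Series(records, name="lineage")


def sample_counts(truth: SyntheticTruth, spec: SyntheticSpec) -> pd.DataFrame:
    """Draw the taxon x sample count table.

    Relative abundances are log-normal; the lowest-abundance
    ``rare_fraction`` of taxa are rescaled so their expected per-sample
    count is below one read.  Within each sample, taxa of the other habitat
    carry weight ``immigrant_weight`` times their base abundance; counts are
    multinomial at a library size drawn uniformly from
    ``library_size_range``, so every column sums to its drawn library size
    exactly.
    """
    rng = np.random.default_rng([_COUNT, spec.seed])
    taxa = truth.taxa
    n = len(taxa)
    mu, sigma = spec.abundance_lognormal_mu_sigma
    weights = rng.lognormal(mu, sigma, size=n)
    rel = weights / weights.sum()
    mean_lib = float(np.mean(spec.library_size_range))
    k_rare = int(round(spec.rare_fraction * n))
    if k_rare:
        order = np.argsort(rel)
        rare_idx = order[:k_rare]
        common_idx = order[k_rare:]
        rare_rel = rng.uniform(0.05, 0.9, size=k_rare) / mean_lib
        rel[rare_idx] = rare_rel
        rel[common_idx] *= (1.0 - rare_rel.sum()) / rel[common_idx].sum()
    home = np.array([truth.habitats[t] for t in taxa])
    samples = [f"M{i + 1:02d}" for i in range(spec.n_marine_samples)] + [
        f"F{i + 1:02d}" for i in range(spec.n_freshwater_samples)
    ]
    lo, hi = spec.library_size_range
    cols = {}
    for sample in samples:
        habitat = "marine" if sample.startswith("M") else "freshwater"
        w = rel * np.where(home == habitat, 1.0, spec.immigrant_weight)
        lib = int(rng.integers(lo, hi + 1))
        if w.sum() == 0:
            # a habitat with no resident taxa and no immigration yields an
            # empty library; downstream filtering drops such samples
            warnings.warn(f"sample {sample} has no taxa to draw from; empty column")
            cols[sample] = np.zeros(n, dtype=np.int64)
            continue
        cols[sample] = rng.multinomial(lib, w / w.sum())
    counts = pd.DataFrame(cols, index=taxa)
    marine_cols = [s for s in samples if s.startswith("M")]
    fresh_cols = [s for s in samples if s.startswith("F")]
    shared = (counts[marine_cols] > 0).any(axis=1) & (counts[fresh_cols] > 0).any(axis=1)
    truth.expected_shared_taxa = list(counts.index[shared])
    return counts


def sample_metadata(spec: SyntheticSpec) -> pd.DataFrame:
    """Per-sample metadata: habitat, one site per sample, cycling depth class."""
    rows = []
    depths = ["surface", "deep"]
    for i in range(spec.n_marine_samples):
        rows.append((f"M{i + 1:02d}", "marine", f"site_M{i + 1:02d}", depths[i % 2]))
    for i in range(spec.n_freshwater_samples):
        rows.append((f"F{i + 1:02d}", "freshwater", f"site_F{i + 1:02d}", depths[i % 2]))
    return pd.DataFrame(rows, columns=["sample_id", "habitat", "site", "depth_class"])


@dataclass
class SimulatedCommunity:
    """Bundle of one generator run: tree, truth, alignment, counts, metadata."""

    spec: SyntheticSpec
    tree: TreeNode
    truth: SyntheticTruth
    seqs: AlignedSequenceSet
    counts: pd.DataFrame
    metadata: pd.DataFrame
    lineage: pd.Series


def simulate_community(
    spec: SyntheticSpec, transition_nodes: list[str] | None = None
) -> SimulatedCommunity:
    """Run the full generator: tree, habitats, sequences, counts, metadata."""
    tree = simulate_tree(spec)
    truth = assign_habitats(tree, spec, transition_nodes=transition_nodes)
    seqs = evolve_sequences(tree, spec)
    realized_transition_divergences(truth, seqs)
    counts = sample_counts(truth, spec)
    metadata = sample_metadata(spec)
    lineage = assign_lineage(tree)
    seqs.counts = counts
    seqs.lineage = lineage
    return SimulatedCommunity(
        spec=spec,
        tree=tree,
        truth=truth,
        seqs=seqs,
        counts=counts,
        metadata=metadata,
        lineage=lineage,
    )


def write_community(com: SimulatedCommunity, outdir) -> dict[str, str]:
    """Write FASTA, newick, counts/metadata/lineage TSVs and truth JSON."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "sequences.fasta",
        "tree": out / "tree.nwk",
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "lineage": out / "lineage.tsv",
        "truth": out / "truth.json",
        "spec": out / "spec.json",
    }
    com.seqs.to_fasta(paths["fasta"])
    com.tree.write(str(paths["tree"]))
    com.counts.rename_axis("taxon_id").to_csv(paths["counts"], sep="\t")
    com.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    com.lineage.rename_axis("taxon_id").rename("lineage").to_csv(paths["lineage"], sep="\t")
    com.truth.to_json(paths["truth"])
    with open(paths["spec"], "w") as fh:
        json.dump(com.spec.to_dict(), fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
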