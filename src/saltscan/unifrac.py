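"""Phylogenetic beta diversity: UniFrac, rarefaction, null models, PerMANOVA.

UniFrac measures the fraction of a rooted tree's branch length unique to one
of two assemblages (unweighted) or the abundance-weighted branch differences
(weighted, normalized).  Habitat structure is tested two ways: PerMANOVA on
the sample-pair distance matrix, and one-sample z-tests of the pooled-habitat
UniFrac against an ensemble of independent-swap randomizations of the
presence-absence matrix (which preserve every taxon's occupancy and every
sample's richness exactly).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode


# ---------------------------------------------------------------------------
# UniFrac proper
# ---------------------------------------------------------------------------

def _tip_index(tree: TreeNode) -> dict[str, int]:
    return {tip.name: i for i, tip in enumerate(tree.tips())}


def _branch_totals(tree: TreeNode, weights: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch lengths and subtree weight sums, postorder, root excluded."""
    lengths = []
    sums = []
    totals: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            totals[id(node)] = float(weights.get(node.name, 0.0))
        else:
            totals[id(node)] = sum(totals[id(c)] for c in node.children)
        if node.parent is not None:  # root's stem carries no information
            lengths.append(node.length or 0.0)
            sums.append(totals[id(node)])
    return np.asarray(lengths), np.asarray(sums)


def _validate_taxa(tree: TreeNode, taxa) -> None:
    tips = {t.name for t in tree.tips()}
    extra = set(taxa) - tips
    if extra:
        raise KeyError(f"taxa absent from tree: {sorted(extra)[:5]}")


def unweighted_unifrac(tree: TreeNode, presence_a, presence_b) -> float:
    """Fraction of branch length unique to one assemblage.

    ``presence_a``/``presence_b`` are iterables of tip names.  Equals 1
    exactly when the two supported tip sets induce no shared branch, and 0
    for identical tip sets.
    """
    set_a, set_b = set(presence_a), set(presence_b)
    if not set_a or not set_b:
        raise ValueError("unweighted UniFrac requires two non-empty assemblages")
    _validate_taxa(tree, set_a | set_b)
    lengths, in_a = _branch_totals(tree, {t: 1.0 for t in set_a})
    _, in_b = _branch_totals(tree, {t: 1.0 for t in set_b})
    has_a, has_b = in_a > 0, in_b > 0
    either = float(lengths[has_a | has_b].sum())
    unique = float(lengths[has_a ^ has_b].sum())
    if either == 0:
        raise ValueError("assemblages touch no branch with positive length")
    return unique / either


def weighted_unifrac(tree: TreeNode, counts_a: dict, counts_b: dict) -> float:
    """Normalized weighted UniFrac.

    sum_b len_b * |p_A - p_B| / sum_b len_b * (p_A + p_B), where p_X is the
    fraction of assemblage X's total descending through branch b.
    """
    tot_a = float(sum(counts_a.values()))
    tot_b = float(sum(counts_b.values()))
    if tot_a <= 0 or tot_b <= 0:
        raise ValueError("weighted UniFrac requires positive totals")
    _validate_taxa(tree, set(counts_a) | set(counts_b))
    lengths, sum_a = _branch_totals(tree, counts_a)
    _, sum_b = _branch_totals(tree, counts_b)
    p_a, p_b = sum_a / tot_a, sum_b / tot_b
    denom = float((lengths * (p_a + p_b)).sum())
    if denom == 0:
        raise ValueError("assemblages touch no branch with positive length")
    return float((lengths * np.abs(p_a - p_b)).sum()) / denom


def sample_pair_unifrac(
    tree: TreeNode,
    counts: pd.DataFrame,
    weighted: bool = False,
) -> pd.DataFrame:
    """Square UniFrac distance matrix over the columns of a count table."""
    samples = list(counts.columns)
    mat = np.zeros((len(samples), len(samples)))
    vectors = {
        s: counts[s][counts[s] > 0].to_dict() for s in samples
    }
    for i in range(len(samples) - 1):
        for j in range(i + 1, len(samples)):
            a, b = vectors[samples[i]], vectors[samples[j]]
            if weighted:
                d = weighted_unifrac(tree, a, b)
            else:
                d = unweighted_unifrac(tree, set(a), set(b))
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=samples, columns=samples)


def pooled_group_unifrac(
    tree: TreeNode,
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    lineage: pd.Series,
    rank: int,
) -> pd.DataFrame:
    """Pooled-habitat unweighted UniFrac per taxonomic group.

    All marine samples are pooled into one assemblage and all freshwater
    samples into another; the group's subtree is sheared out and the pooled
    unweighted UniFrac computed on it.  Pairwise per-sample distances within
    the group are summarized alongside (median and range).  Groups absent
    from a habitat are flagged not evaluable (NaN distance).
    """
    habitats = metadata.set_index("sample_id")["habitat"]
    marine = [s for s in counts.columns if habitats[s] == "marine"]
    fresh = [s for s in counts.columns if habitats[s] == "freshwater"]
    groups = lineage_groups(lineage, rank)
    records = []
    for group, taxa in groups.items():
        taxa = [t for t in taxa if t in counts.index]
        sub = counts.loc[taxa]
        pooled_m = set(sub.index[(sub[marine] > 0).any(axis=1)])
        pooled_f = set(sub.index[(sub[fresh] > 0).any(axis=1)])
        if not pooled_m or not pooled_f:
            records.append((group, np.nan, False, np.nan, np.nan, np.nan))
            continue
        if pooled_m == pooled_f:
            pooled = 0.0  # identical assemblages; shear would be degenerate
        else:
            subtree = tree.shear(pooled_m | pooled_f)
            pooled = unweighted_unifrac(subtree, pooled_m, pooled_f)
        pairwise = []
        for m in marine:
            for f in fresh:
                pm = set(sub.index[sub[m] > 0])
                pf = set(sub.index[sub[f] > 0])
                if pm and pf:
                    if pm == pf:
                        pairwise.append(0.0)
                    else:
                        pairwise.append(unweighted_unifrac(tree.shear(pm | pf), pm, pf))
        med = float(np.median(pairwise)) if pairwise else np.nan
        lo = float(np.min(pairwise)) if pairwise else np.nan
        hi = float(np.max(pairwise)) if pairwise else np.nan
        records.append((group, pooled, True, med, lo, hi))
    return pd.DataFrame(
        records,
        columns=["group", "pooled_unifrac", "evaluable", "pairwise_median", "pairwise_min", "pairwise_max"],
    ).set_index("group")


def lineage_groups(lineage: pd.Series, rank: int) -> dict[str, list[str]]:
    """Map group label at a 1-based rank (1=phylum .. 5=genus) to taxon ids."""
    if rank < 1:
        raise ValueError("rank must be >= 1 (1=phylum)")
    labels = lineage.str.split(";").str[: rank].str.join(";")
    if (lineage.str.split(";").str.len() < rank).any():
        raise ValueError(f"lineage strings lack rank {rank}")
    out: dict[str, list[str]] = {}
    for taxon, lab in labels.items():
        out.setdefault(lab, []).append(taxon)
    return out


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(counts: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample (column) without replacement to an even depth.

    Samples whose total falls below ``depth`` are dropped with a warning,
    matching common practice of rarefying to the smallest retained library.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    kept = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=np.int64)
        total = int(col.sum())
        if total < depth:
            warnings.warn(f"sample {sample!r} dropped: {total} < depth {depth}")
            continue
        reads = np.repeat(np.arange(col.size), col)
        chosen = rng.choice(reads, size=depth, replace=False)
        kept[sample] = np.bincount(chosen, minlength=col.size)
    return pd.DataFrame(kept, index=counts.index, dtype=np.int64)


# ---------------------------------------------------------------------------
# Independent-swap null and tests
# ---------------------------------------------------------------------------

def _has_checkerboard(matrix: np.ndarray) -> bool:
    m = matrix.astype(bool)
    for i in range(m.shape[0] - 1):
        diff_a = m[i] & ~m[i + 1 :]
        diff_b = ~m[i] & m[i + 1 :]
        if (diff_a.any(axis=1) & diff_b.any(axis=1)).any():
            return True
    return False


def independent_swap_null(
    presence: np.ndarray,
    n_rand: int = 1000,
    seed: int = 0,
    burnin_factor: int = 10,
    thin_factor: int = 1,
) -> np.ndarray:
    """Randomize a binary matrix preserving all row and column sums.

    Repeated 2x2 checkerboard submatrix swaps (the classic independent-swap
    chain): burn-in of ``burnin_factor`` x cells swap attempts, then one draw
    every ``thin_factor`` x cells attempts.  Returns an (n_rand, rows, cols)
    array.  A matrix with no swappable checkerboard is returned unchanged
    ``n_rand`` times with a warning.
    """
    mat = np.asarray(presence)
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    mat = mat.astype(np.int8).copy()
    rows, cols = mat.shape
    if rows < 2 or cols < 2 or not _has_checkerboard(mat):
        warnings.warn("no swappable 2x2 checkerboard; returning original matrix")
        return np.repeat(mat[None, :, :], n_rand, axis=0)
    rng = np.random.default_rng(seed)
    cells = rows * cols
    draws = np.empty((n_rand, rows, cols), dtype=np.int8)

    def attempt_block(n_attempts: int) -> None:
        rr = rng.integers(0, rows, size=(n_attempts, 2))
        cc = rng.integers(0, cols, size=(n_attempts, 2))
        for (r1, r2), (c1, c2) in zip(rr, cc):
            if r1 == r2 or c1 == c2:
                continue
            a, b, c, d = mat[r1, c1], mat[r1, c2], mat[r2, c1], mat[r2, c2]
            if a == d and b == c and a != b:
                mat[r1, c1] = b
                mat[r1, c2] = a
                mat[r2, c1] = d
                mat[r2, c2] = c

    attempt_block(burnin_factor * cells)
    for k in range(n_rand):
        attempt_block(thin_factor * cells)
        draws[k] = mat
    return draws


def z_test(observed: float, null_values, n_groups: int = 1) -> tuple[float, float, float]:
    """One-sample z-test of an observed statistic against a null ensemble.

    One-sided upper tail (habitat structure inflates between-habitat UniFrac
    above its null).  Bonferroni multiplies p by the number of groups tested,
    capped at 1.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size < 2:
        raise ValueError("need at least 2 null values")
    mu = float(null_values.mean())
    sigma = float(null_values.std(ddof=1))
    if sigma == 0:
        raise ValueError("degenerate null ensemble: zero standard deviation")
    z = (observed - mu) / sigma
    p = float(stats.norm.sf(z))
    return z, p, min(1.0, p * n_groups)


def permanova(
    dm: np.ndarray | pd.DataFrame,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Permutational multivariate ANOVA (adonis-style) on a distance matrix.

    pseudo-F = (SS_between/(k-1)) / (SS_within/(N-k)) with
    SS_total = sum_{i<j} d_ij^2 / N and SS_within accumulated per group;
    R^2 = SS_between / SS_total.  The p-value permutes labels:
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    mat = np.asarray(dm.values if isinstance(dm, pd.DataFrame) else dm, dtype=float)
    n = mat.shape[0]
    if mat.shape != (n, n) or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("PerMANOVA needs at least two groups")
    if np.bincount(inv).min() < 2:
        raise ValueError("every group needs at least two samples")
    sq = mat ** 2
    iu = np.triu_indices(n, 1)
    ss_total = sq[iu].sum() / n

    def ss_within(assignment: np.ndarray) -> float:
        total = 0.0
        for g in range(k):
            idx = np.nonzero(assignment == g)[0]
            total += sq[np.ix_(idx, idx)].sum() / (2 * idx.size)
        return total

    def pseudo_f(assignment: np.ndarray) -> float:
        sw = ss_within(assignment)
        with np.errstate(divide="ignore"):
            # perfectly separated groups (zero within-group distance) give F=inf
            return float(((ss_total - sw) / (k - 1)) / (np.float64(sw) / (n - k)))

    f_obs = pseudo_f(inv)
    r2 = float((ss_total - ss_within(inv)) / ss_total)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(inv)) >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(f_obs), float(r2), float(p)
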