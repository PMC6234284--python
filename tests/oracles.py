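"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a deliberately different route from the
implementation it checks: complete linkage by a dict-of-sets pure-Python
agglomerator, UniFrac by explicit enumeration of every branch's descendant
tip set, and the shared-identity scan by walking the cutoff grid and testing
cluster-level Jaccard sharing directly.
"""

from __future__ import annotations

import math


def complete_linkage_oracle(dist: dict[tuple[int, int], float], n: int):
    """O(n^3) complete-linkage agglomeration over items 0..n-1.

    ``dist`` maps (i, j) with i < j to a distance.  Returns the merge list
    [(height, members_frozenset)] with the same tie-break as the library:
    smallest linkage first, then the pair whose smallest members come first.
    """

    def d(i, j):
        return dist[(i, j)] if i < j else dist[(j, i)]

    clusters: list[set[int]] = [{i} for i in range(n)]
    merges = []
    while len(clusters) > 1:
        candidates = []
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                linkage = max(d(i, j) for i in clusters[a] for j in clusters[b])
                lo = min(min(clusters[a]), min(clusters[b]))
                hi = max(min(clusters[a]), min(clusters[b]))
                candidates.append((linkage, lo, hi, a, b))
        vmin = min(c[0] for c in candidates)
        linkage, _, _, a, b = min(
            (c for c in candidates if c[0] <= vmin + 1e-12), key=lambda c: (c[1], c[2])
        )
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        merges.append((linkage, frozenset(merged)))
    return merges


def partition_oracle(merges, n: int, cutoff: float):
    """Partition implied by oracle merges at a cutoff (apply merges <= cutoff)."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for height, members in merges:
        if height > cutoff + 1e-12:
            break
        members = sorted(members)
        for m in members[1:]:
            parent[find(m)] = find(members[0])
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(frozenset(g) for g in groups.values())


def unifrac_oracle(tree, a, b, weighted=False):
    """UniFrac by explicit per-branch descendant-set enumeration."""
    tot_a = sum(a.values()) if weighted else None
    tot_b = sum(b.values()) if weighted else None
    num = 0.0
    den = 0.0
    for node in tree.traverse(include_self=True):
        if node.parent is None:
            continue
        length = node.length or 0.0
        tips = {t.name for t in node.tips()} or {node.name}
        if weighted:
            pa = sum(a.get(t, 0.0) for t in tips) / tot_a
            pb = sum(b.get(t, 0.0) for t in tips) / tot_b
            num += length * abs(pa - pb)
            den += length * (pa + pb)
        else:
            in_a = bool(tips & a)
            in_b = bool(tips & b)
            if in_a or in_b:
                den += length
                if in_a != in_b:
                    num += length
    return num / den


def scan_oracle(clustering, present_a: set, present_b: set) -> float:
    """Max shared identity by walking the grid and testing Jaccard sharing."""
    for cutoff in clustering.cutoffs:
        partition = clustering.partition_at(cutoff)
        for members in partition.values():
            ms = set(members)
            if ms & present_a and ms & present_b:
                return round(1.0 - cutoff, 12)
    raise AssertionError("no sharing even at the collapse cutoff")


def binom_pmf(n: int, p: float, k: int) -> float:
    """Exact binomial pmf via log-gamma, independent of scipy."""
    if p == 0:
        return 1.0 if k == 0 else 0.0
    log = (
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )
    return math.exp(log)
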