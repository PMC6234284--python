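"""Farthest-neighbor (complete-linkage) clustering at every identity cutoff.

A merge at cutoff t requires ALL cross-pair distances <= t, so a cluster at a
given cutoff is a set of sequences whose diameter does not exceed the cutoff.
Partitions are emitted on a fixed distance grid (default step 0.001, i.e.
identity precision of one part in a thousand) from 0 up to the first grid
point at which all sequences collapse into one cluster.  Merge order is
deterministic: among tied candidate merges the pair whose smallest member
comes first in the input ordering wins (then the other member).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix

_TIE_EPS = 1e-12


@dataclass
class MultiThresholdClustering:
    """Complete-linkage merge tree evaluated on a distance-cutoff grid.

    ``merges`` holds the (height, left, right) agglomeration steps over
    cluster indices: leaves are 0..n-1 in input order, the k-th merge creates
    cluster n+k.  Heights are non-decreasing (complete linkage is monotone).
    """

    ids: list[str]
    merges: list[tuple[float, int, int]]
    grid_step: float
    _members: list[list[int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        members: list[list[int]] = [[i] for i in range(n)]
        for _, a, b in self.merges:
            members.append(sorted(members[a] + members[b]))
        self._members = members

    @property
    def collapse_height(self) -> float:
        """Smallest distance at which a single cluster remains."""
        return self.merges[-1][0] if self.merges else 0.0

    @property
    def cutoffs(self) -> np.ndarray:
        """Grid cutoffs from 0 up to (and including) the collapse point."""
        top = self.grid_cutoff(self.collapse_height)
        n_steps = int(round(top / self.grid_step))
        return np.round(np.arange(n_steps + 1) * self.grid_step, 12)

    def grid_cutoff(self, height: float) -> float:
        """Smallest grid cutoff at which a merge of this height is applied."""
        k = int(np.ceil(height / self.grid_step - _TIE_EPS))
        return round(max(k, 0) * self.grid_step, 12)

    def labels_at(self, cutoff: float) -> np.ndarray:
        """Cluster label per sequence (labels are smallest member indices)."""
        n = len(self.ids)
        parent = np.arange(n)
        for k, (height, _, _) in enumerate(self.merges):
            if height > cutoff + _TIE_EPS:
                break
            merged = self._members[n + k]
            parent[merged] = merged[0]
        return parent

    def partition_at(self, cutoff: float) -> dict[str, list[str]]:
        labels = self.labels_at(cutoff)
        out: dict[str, list[str]] = {}
        for i, lab in enumerate(labels):
            out.setdefault(self.ids[lab], []).append(self.ids[i])
        return out

    def n_clusters_at(self, cutoff: float) -> int:
        return len(np.unique(self.labels_at(cutoff)))

    def check_nested(self) -> None:
        """Assert partitions are nested and cluster counts non-increasing."""
        prev = None
        prev_n = None
        for cutoff in self.cutoffs:
            labels = self.labels_at(cutoff)
            n_clust = len(np.unique(labels))
            if prev is not None:
                if prev_n < n_clust:
                    raise AssertionError("cluster count increased along the grid")
                # every cluster at the previous (finer) cutoff maps into one cluster
                for lab in np.unique(prev):
                    if len(np.unique(labels[prev == lab])) != 1:
                        raise AssertionError("partitions not nested across cutoffs")
            prev, prev_n = labels, n_clust


def farthest_neighbor_cluster(
    dm: DistanceMatrix | np.ndarray,
    grid_step: float = 0.001,
    ids: list[str] | None = None,
) -> MultiThresholdClustering:
    """Complete-linkage agglomeration of a pairwise distance matrix.

    At every step the pair of clusters with the smallest complete linkage
    (maximum cross-pair distance) is merged; ties are broken by the lowest
    pair of smallest-member positions in the input order.  The returned
    object exposes partitions on the cutoff grid.
    """
    if not 0 < grid_step <= 0.01:
        raise ValueError("grid_step must be in (0, 0.01]")
    if isinstance(dm, DistanceMatrix):
        mat = np.asarray(dm.data, dtype=float).copy()
        ids = list(dm.ids)
    else:
        mat = np.asarray(dm, dtype=float).copy()
        if ids is None:
            ids = [f"s{i}" for i in range(mat.shape[0])]
    n = mat.shape[0]
    if n == 0:
        raise ValueError("empty distance matrix")
    if mat.shape != (n, n) or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")

    np.fill_diagonal(mat, np.inf)
    active = np.ones(n, dtype=bool)
    minmem = np.arange(n)          # smallest original member per slot
    slot_cluster = np.arange(n)    # cluster index (merge-tree numbering) per slot
    merges: list[tuple[float, int, int]] = []
    for step in range(n - 1):
        sub = np.where(active[:, None] & active[None, :], mat, np.inf)
        height = float(sub.min())
        cand = np.argwhere(np.triu(sub <= height + _TIE_EPS, k=1))
        lo = np.minimum(minmem[cand[:, 0]], minmem[cand[:, 1]])
        hi = np.maximum(minmem[cand[:, 0]], minmem[cand[:, 1]])
        pick = np.lexsort((hi, lo))[0]
        i, j = int(cand[pick, 0]), int(cand[pick, 1])
        if minmem[j] < minmem[i]:
            i, j = j, i
        if merges and height < merges[-1][0]:
            height = merges[-1][0]  # guard against fp jitter; CL is monotone
        merges.append((height, int(slot_cluster[i]), int(slot_cluster[j])))
        new = np.maximum(mat[i], mat[j])
        mat[i] = new
        mat[:, i] = new
        mat[i, i] = np.inf
        active[j] = False
        minmem[i] = min(minmem[i], minmem[j])
        slot_cluster[i] = n + step
    return MultiThresholdClustering(ids=ids, merges=merges, grid_step=grid_step)
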