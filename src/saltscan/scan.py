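"""Cross-habitat shared-identity scan.

For a marine-freshwater sample pair, the statistic is the highest sequence
identity cutoff at which the two samples still share at least one cluster
(equivalently, the finest clustering at which their Jaccard distance drops
below 1).  Sharing at high identity implies a recent habitat transition in
that group; a low maximum shared identity implies an ancient split into
exclusively marine and exclusively freshwater clades.  Identity and distance
cutoffs are two currencies for the same grid: identity = 1 - distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from saltscan.cluster import MultiThresholdClustering


def jaccard_distance(sample_a: set, sample_b: set) -> float:
    """1 - |A n B| / |A u B|; equals 1 exactly when no units are shared."""
    a, b = set(sample_a), set(sample_b)
    union = a | b
    if not union:
        raise ValueError("Jaccard distance undefined for two empty samples")
    return 1.0 - len(a & b) / len(union)


def _present_ids(counts: pd.DataFrame, sample: str, universe: list[str]) -> set[str]:
    if sample not in counts.columns:
        raise KeyError(f"sample {sample!r} absent from count table")
    col = counts.loc[counts.index.intersection(universe), sample]
    return set(col.index[col > 0])


def pair_scan(
    clustering: MultiThresholdClustering,
    counts: pd.DataFrame,
    marine_id: str,
    freshwater_id: str,
) -> float:
    """Maximum shared-identity threshold for one marine-freshwater pair.

    Walks the cutoff grid from finest (identity 1.0) to coarsest and returns
    1 - cutoff at the first cutoff where some cluster contains a sequence
    observed (count > 0) in each sample.  Because the merge tree collapses to
    one cluster at its top, a value always exists when both samples contain
    sequences of the group; a sample with no group sequences is an error.
    """
    present_a = _present_ids(counts, marine_id, clustering.ids)
    present_b = _present_ids(counts, freshwater_id, clustering.ids)
    if not present_a:
        raise ValueError(f"sample {marine_id!r} has no sequences in this group")
    if not present_b:
        raise ValueError(f"sample {freshwater_id!r} has no sequences in this group")
    if present_a & present_b:
        return 1.0
    index = {sid: i for i, sid in enumerate(clustering.ids)}
    n = len(clustering.ids)
    has_a = np.zeros(2 * n - 1, dtype=bool)
    has_b = np.zeros(2 * n - 1, dtype=bool)
    for sid in present_a:
        has_a[index[sid]] = True
    for sid in present_b:
        has_b[index[sid]] = True
    for k, (height, left, right) in enumerate(clustering.merges):
        node = n + k
        has_a[node] = has_a[left] or has_a[right]
        has_b[node] = has_b[left] or has_b[right]
        if has_a[node] and has_b[node]:
            return round(1.0 - clustering.grid_cutoff(height), 12)
    # unreachable for non-empty samples: the final merge holds every sequence
    raise AssertionError("merge tree did not collapse to a single cluster")


@dataclass
class ScanResult:
    """Per-group scan over all marine-freshwater sample pairs."""

    group: str
    pairs: pd.DataFrame  # columns: marine, freshwater, max_shared_identity
    n_pairs_skipped: int
    n_marine_present: int
    n_freshwater_present: int
    evaluable: bool
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = self.pairs["max_shared_identity"].to_numpy(dtype=float)
        if values.size:
            self.summary = {
                "median": float(np.median(values)),
                "q1": float(np.quantile(values, 0.25)),
                "q3": float(np.quantile(values, 0.75)),
                "min": float(values.min()),
                "max": float(values.max()),
                "n_pairs": int(values.size),
            }


def group_scan(
    clusterings: dict[str, MultiThresholdClustering],
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
) -> list[ScanResult]:
    """Scan every marine-freshwater sample pair within each group.

    ``clusterings`` maps a group label (phylum, or proteobacterial class) to
    the complete-linkage clustering of that group's sequences.  Pairs where
    either sample lacks the group are skipped and tallied, mirroring the
    per-group sample-presence counts that accompany the box-plot summaries.
    """
    habitats = metadata.set_index("sample_id")["habitat"] if "sample_id" in metadata else metadata["habitat"]
    missing = set(counts.columns) - set(habitats.index)
    if missing:
        raise KeyError(f"metadata missing samples: {sorted(missing)}")
    marine = [s for s in counts.columns if habitats[s] == "marine"]
    fresh = [s for s in counts.columns if habitats[s] == "freshwater"]
    results = []
    for group, clustering in clusterings.items():
        universe = clustering.ids
        present = {s: bool(_present_ids(counts, s, universe)) for s in counts.columns}
        m_present = [s for s in marine if present[s]]
        f_present = [s for s in fresh if present[s]]
        records = []
        skipped = 0
        for m in marine:
            for f in fresh:
                if present[m] and present[f]:
                    records.append((m, f, pair_scan(clustering, counts, m, f)))
                else:
                    skipped += 1
        results.append(
            ScanResult(
                group=group,
                pairs=pd.DataFrame(records, columns=["marine", "freshwater", "max_shared_identity"]),
                n_pairs_skipped=skipped,
                n_marine_present=len(m_present),
                n_freshwater_present=len(f_present),
                evaluable=bool(m_present) and bool(f_present),
            )
        )
    return results
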