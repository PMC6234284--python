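"""Pairwise identity distances on aligned 16S-like sequences.

Distances follow the mothur-style "one-gap" convention: a maximal run of gap
columns present in only one of the two sequences counts as a single
difference, terminal gaps are ignored, and columns gapped in both sequences
are skipped.  The denominator is the number of alignment columns (inside the
shared non-terminal span) with a non-gap character in at least one sequence.
Columns containing N in either sequence are excluded from the comparison
entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

_ALPHABET = "ACGT-N"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_CODE["."] = _CODE["-"]  # terminal-gap notation used by some aligners
GAP = _CODE["-"]
AMBIG = _CODE["N"]


def encode_alignment(sequences: list[str]) -> np.ndarray:
    """Encode equal-length aligned sequences as a (n, L) uint8 matrix."""
    if not sequences:
        raise ValueError("empty alignment")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("aligned sequences must all have the same length")
    lut = np.full(256, 255, dtype=np.uint8)
    for char, code in _CODE.items():
        lut[ord(char)] = code
        lut[ord(char.lower())] = code
    mat = lut[np.frombuffer("".join(sequences).encode(), dtype=np.uint8)]
    if (mat == 255).any():
        bad = set("".join(sequences)) - set(_ALPHABET + _ALPHABET.lower() + ".")
        raise ValueError(f"alphabet outside {{A,C,G,T,-,N}}: {sorted(bad)}")
    return mat.reshape(len(sequences), length)


def decode_row(row: np.ndarray) -> str:
    return "".join(_ALPHABET[c] for c in row)


@dataclass
class AlignedSequenceSet:
    """Equal-length aligned sequences plus optional per-sequence counts and lineage.

    ``counts`` is a taxon x sample integer DataFrame indexed by sequence id;
    ``lineage`` maps sequence id to a semicolon-delimited rank string
    (phylum;class;order;family;genus).
    """

    ids: list[str]
    sequences: list[str]
    counts: pd.DataFrame | None = None
    lineage: pd.Series | None = None
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("sequence ids must be unique")
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences length mismatch")
        self._matrix = encode_alignment(self.sequences)

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    @property
    def alignment_length(self) -> int:
        return self._matrix.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, keep: list[str]) -> "AlignedSequenceSet":
        index = {sid: i for i, sid in enumerate(self.ids)}
        rows = [index[sid] for sid in keep]
        return AlignedSequenceSet(
            ids=list(keep),
            sequences=[self.sequences[i] for i in rows],
            counts=None if self.counts is None else self.counts.loc[keep],
            lineage=None if self.lineage is None else self.lineage.loc[keep],
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.sequences):
                fh.write(f">{sid}\n{seq}\n")

    @classmethod
    def from_fasta(cls, path, counts=None, lineage=None) -> "AlignedSequenceSet":
        ids: list[str] = []
        seqs: list[str] = []
        current: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if ids:
                        seqs.append("".join(current))
                    ids.append(line[1:].split()[0])
                    current = []
                else:
                    current.append(line.upper())
            if ids:
                seqs.append("".join(current))
        return cls(ids=ids, sequences=seqs, counts=counts, lineage=lineage)


def _pair_distance(a: np.ndarray, b: np.ndarray) -> float:
    """One-gap distance between two encoded rows."""
    nongap_a = np.nonzero(a != GAP)[0]
    nongap_b = np.nonzero(b != GAP)[0]
    if nongap_a.size == 0 or nongap_b.size == 0:
        return 0.0
    start = max(nongap_a[0], nongap_b[0])
    stop = min(nongap_a[-1], nongap_b[-1])
    if stop < start:
        return 0.0
    a = a[start : stop + 1]
    b = b[start : stop + 1]
    keep = ~((a == GAP) & (b == GAP)) & (a != AMBIG) & (b != AMBIG)
    a = a[keep]
    b = b[keep]
    if a.size == 0:
        return 0.0
    gap_a = a == GAP
    gap_b = b == GAP
    base_mismatch = int(np.count_nonzero(~gap_a & ~gap_b & (a != b)))
    # each maximal run of one-sided gap columns contributes one difference
    runs_a = int(np.count_nonzero(np.diff(np.concatenate(([0], gap_a.view(np.int8)))) == 1))
    runs_b = int(np.count_nonzero(np.diff(np.concatenate(([0], gap_b.view(np.int8)))) == 1))
    return (base_mismatch + runs_a + runs_b) / a.size


def pairwise_distance(seqs: AlignedSequenceSet) -> DistanceMatrix:
    """All-versus-all fractional sequence distances under the one-gap rule.

    Returns a zero-diagonal symmetric :class:`skbio.DistanceMatrix` keyed by
    sequence id, with every entry in [0, 1].
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    mat = seqs.matrix
    out = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _pair_distance(mat[i], mat[j])
    return DistanceMatrix(out, ids=seqs.ids)


def raw_differences(a: np.ndarray, b: np.ndarray) -> int:
    """Number of alignment columns at which two encoded rows differ."""
    return int(np.count_nonzero(a != b))


def precluster(seqs: AlignedSequenceSet, max_diffs: int = 2) -> AlignedSequenceSet:
    """Greedy abundance-sorted denoising merge.

    Sequences are visited from most to least abundant (total count across
    samples; input order breaks ties); each is absorbed by the first retained
    representative within ``max_diffs`` raw column differences, its counts
    summed onto that representative.  Mirrors mothur's pre.cluster step.
    """
    if max_diffs < 0:
        raise ValueError("max_diffs must be >= 0")
    if seqs.counts is None:
        raise ValueError("precluster requires per-sequence counts")
    counts = seqs.counts.reindex(seqs.ids)
    totals = counts.sum(axis=1)
    order = sorted(range(len(seqs)), key=lambda i: (-int(totals.iloc[i]), i))
    mat = seqs.matrix
    reps: list[int] = []
    absorbed: dict[int, list[int]] = {}
    for i in order:
        home = None
        for r in reps:
            if raw_differences(mat[i], mat[r]) <= max_diffs:
                home = r
                break
        if home is None:
            reps.append(i)
            absorbed[i] = [i]
        else:
            absorbed[home].append(i)
    reps_sorted = sorted(reps)
    new_ids = [seqs.ids[r] for r in reps_sorted]
    new_counts = pd.DataFrame(
        [counts.iloc[absorbed[r]].sum(axis=0) for r in reps_sorted],
        index=new_ids,
    )
    return AlignedSequenceSet(
        ids=new_ids,
        sequences=[seqs.sequences[r] for r in reps_sorted],
        counts=new_counts,
        lineage=None if seqs.lineage is None else seqs.lineage.loc[new_ids],
    )
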