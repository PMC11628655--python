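"""Vectorized half-open interval arithmetic on a linearized genome.

The permutation engine needs tens of thousands of overlap evaluations, so
intervals are mapped onto a single concatenated coordinate axis (one offset
per chromosome) and all queries reduce to ``np.searchsorted`` against the
merged feature set.  Placement never lets an interval span a chromosome
boundary, so linearization is lossless.
"""

from __future__ import annotations

import numpy as np

from .model import GenomeAssembly


class LinearGenome:
    """Chromosomes laid end to end on one integer axis."""

    def __init__(self, assembly: GenomeAssembly):
        self.assembly = assembly
        self.chrom_ids = [c for c, _ in assembly.chromosomes]
        self.lengths = np.array([n for _, n in assembly.chromosomes], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)[:-1]])
        self.total = int(self.lengths.sum())
        self._index = {c: i for i, c in enumerate(self.chrom_ids)}

    def to_linear(self, chrom, start, end=None):
        i = self._index[chrom]
        off = int(self.offsets[i])
        if end is None:
            return off + int(start)
        return off + int(start), off + int(end)

    def linearize(self, intervals) -> np.ndarray:
        """(chrom, start, end) triples -> (n, 2) linear array."""
        out = np.empty((len(intervals), 2), dtype=np.int64)
        for k, (chrom, s, e) in enumerate(intervals):
            out[k] = self.to_linear(chrom, s, e)
        return out

    def delinearize_point(self, pos: int):
        i = int(np.searchsorted(self.offsets, pos, side="right")) - 1
        return self.chrom_ids[i], int(pos - self.offsets[i])


def merge(arr: np.ndarray) -> np.ndarray:
    """Merge possibly-overlapping linear intervals; returns sorted (m, 2)."""
    if len(arr) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    starts, ends = [], []
    cs, ce = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        if s <= ce:
            ce = max(ce, int(e))
        else:
            starts.append(cs)
            ends.append(ce)
            cs, ce = int(s), int(e)
    starts.append(cs)
    ends.append(ce)
    return np.column_stack([np.array(starts, dtype=np.int64),
                            np.array(ends, dtype=np.int64)])


class MergedSet:
    """A merged feature set supporting batched overlap queries."""

    def __init__(self, intervals: np.ndarray):
        m = merge(np.asarray(intervals, dtype=np.int64).reshape(-1, 2))
        self.starts = m[:, 0]
        self.ends = m[:, 1]
        lengths = self.ends - self.starts
        self.prefix = np.concatenate([[0], np.cumsum(lengths)])
        self.total_bases = int(self.prefix[-1])

    def __len__(self) -> int:
        return len(self.starts)

    def base_overlap(self, qstarts: np.ndarray, qends: np.ndarray) -> np.ndarray:
        """Bases of overlap between each query interval and the set."""
        qstarts = np.asarray(qstarts, dtype=np.int64)
        qends = np.asarray(qends, dtype=np.int64)
        i = np.searchsorted(self.ends, qstarts, side="right")
        j = np.searchsorted(self.starts, qends, side="left")
        out = np.zeros(len(qstarts), dtype=np.int64)
        hit = i < j
        if hit.any():
            ih, jh = i[hit], j[hit]
            tot = self.prefix[jh] - self.prefix[ih]
            tot -= np.maximum(0, qstarts[hit] - self.starts[ih])
            tot -= np.maximum(0, self.ends[jh - 1] - qends[hit])
            out[hit] = tot
        return out

    def any_overlap(self, qstarts: np.ndarray, qends: np.ndarray) -> np.ndarray:
        qstarts = np.asarray(qstarts, dtype=np.int64)
        qends = np.asarray(qends, dtype=np.int64)
        i = np.searchsorted(self.ends, qstarts, side="right")
        j = np.searchsorted(self.starts, qends, side="left")
        return i < j
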