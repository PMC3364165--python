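"""Kimura 2-parameter distances with pairwise deletion, and distance-matrix
utilities (single-linkage clustering at a divergence cutoff, shared-haplotype
detection, TSV export).

For a pair of sequences only sites where both carry a concrete A/C/G/T base
are compared (pairwise deletion); with transition proportion P and
transversion proportion Q over those n sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

A pair is *undefined* when the overlap n falls below ``min_overlap`` or a
logarithm argument is non-positive (saturation).  Undefined entries are
carried as NaN and must be handled explicitly by downstream consumers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_io_qc import AnchoredSequence

__all__ = [
    "K2PComputation",
    "DistanceMatrix",
    "DEFAULT_MIN_OVERLAP",
    "k2p_from_counts",
    "k2p_distance",
    "build_distance_matrix",
    "single_linkage_clusters",
    "detect_shared_haplotypes",
]

DEFAULT_MIN_OVERLAP = 100


@dataclass(frozen=True)
class K2PComputation:
    """Site counts and the resulting K2P distance for one sequence pair."""

    n: int
    transitions: int
    transversions: int
    d: float | None

    @property
    def P(self) -> float:
        return self.transitions / self.n if self.n else math.nan

    @property
    def Q(self) -> float:
        return self.transversions / self.n if self.n else math.nan

    @property
    def defined(self) -> bool:
        return self.d is not None


def k2p_from_counts(n: int, transitions: int, transversions: int) -> float | None:
    """Evaluate the K2P formula from site counts; None when saturated."""
    if n <= 0:
        return None
    P = transitions / n
    Q = transversions / n
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return None
    return -0.5 * math.log(a) - 0.25 * math.log(b)


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    both = (x < 4) & (y < 4)
    xs, ys = x[both], y[both]
    diff = xs != ys
    # transition iff same parity (A/G even, C/T odd)
    ts = int(np.count_nonzero(diff & ((xs & 1) == (ys & 1))))
    tv = int(np.count_nonzero(diff)) - ts
    return int(both.sum()), ts, tv


def k2p_distance(
    a: AnchoredSequence,
    b: AnchoredSequence,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> K2PComputation:
    """Pairwise-deletion K2P distance between two frame-anchored sequences."""
    n, ts, tv = _pair_counts(a.frame_codes(), b.frame_codes())
    d = k2p_from_counts(n, ts, tv) if n >= min_overlap else None
    return K2PComputation(n=n, transitions=ts, transversions=tv, d=d)


class DistanceMatrix:
    """Symmetric pairwise K2P distances over an ordered id list.

    ``d`` holds distances with NaN marking undefined entries; ``n``, ``ts``
    and ``tv`` hold the per-pair compared-site and substitution counts.
    """

    def __init__(
        self,
        ids: Sequence[str],
        d: np.ndarray,
        n: np.ndarray,
        ts: np.ndarray,
        tv: np.ndarray,
    ):
        self.ids = list(ids)
        self.d = d
        self.n = n
        self.ts = ts
        self.tv = tv
        self._index = {sid: i for i, sid in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate ids in distance matrix")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        return self._index[specimen_id]

    def get(self, id_a: str, id_b: str) -> float:
        """Distance between two specimens (NaN when undefined)."""
        return float(self.d[self._index[id_a], self._index[id_b]])

    def defined(self, id_a: str, id_b: str) -> bool:
        return not math.isnan(self.get(id_a, id_b))

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self._index[i] for i in ids])
        return DistanceMatrix(
            ids,
            self.d[np.ix_(idx, idx)],
            self.n[np.ix_(idx, idx)],
            self.ts[np.ix_(idx, idx)],
            self.tv[np.ix_(idx, idx)],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_square_tsv(self, path: str | Path) -> None:
        """Square matrix with id header row/column; undefined as NA."""
        df = self.to_dataframe()
        df.to_csv(path, sep="\t", na_rep="NA", index_label="specimen_id")

    def write_long_tsv(self, path: str | Path) -> None:
        """Long format: id1, id2, n, P, Q, d for each unordered pair."""
        rows = []
        m = len(self.ids)
        for i in range(m):
            for j in range(i + 1, m):
                n = int(self.n[i, j])
                rows.append(
                    {
                        "id1": self.ids[i],
                        "id2": self.ids[j],
                        "n": n,
                        "P": self.ts[i, j] / n if n else math.nan,
                        "Q": self.tv[i, j] / n if n else math.nan,
                        "d": self.d[i, j],
                    }
                )
        pd.DataFrame(rows, columns=["id1", "id2", "n", "P", "Q", "d"]).to_csv(
            path, sep="\t", na_rep="NA", index=False
        )


def build_distance_matrix(
    seqs: Sequence[AnchoredSequence],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """All-pairs pairwise-deletion K2P matrix.

    Vectorised over the 658-site frame; requires at least two sequences.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    ids = [s.specimen_id for s in seqs]
    codes = np.stack([s.frame_codes() for s in seqs])  # (m, 658)
    m = codes.shape[0]
    concrete = codes < 4
    parity = codes & 1

    n = np.zeros((m, m), dtype=np.int64)
    ts = np.zeros((m, m), dtype=np.int64)
    tv = np.zeros((m, m), dtype=np.int64)
    # row-blocked broadcasting keeps peak memory modest for large libraries
    block = max(1, 2**22 // max(1, m * codes.shape[1]))
    for lo in range(0, m, block):
        hi = min(m, lo + block)
        both = concrete[lo:hi, None, :] & concrete[None, :, :]
        diff = (codes[lo:hi, None, :] != codes[None, :, :]) & both
        same_parity = parity[lo:hi, None, :] == parity[None, :, :]
        n[lo:hi] = both.sum(axis=2)
        ts[lo:hi] = (diff & same_parity).sum(axis=2)
        tv[lo:hi] = diff.sum(axis=2) - ts[lo:hi]

    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n > 0, ts / np.maximum(n, 1), np.nan)
        Q = np.where(n > 0, tv / np.maximum(n, 1), np.nan)
        a = 1.0 - 2.0 * P - Q
        b = 1.0 - 2.0 * Q
        d = np.where(
            (a > 0) & (b > 0), -0.5 * np.log(np.abs(a)) - 0.25 * np.log(np.abs(b)), np.nan
        )
    d[n < min_overlap] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d, n, ts, tv)


def single_linkage_clusters(
    matrix: DistanceMatrix,
    ids: Sequence[str] | None = None,
    cutoff: float = 0.05,
) -> list[list[str]]:
    """Partition ids into chains connected by pairs with d < cutoff (strict).

    Clusters are returned sorted by (and internally sorted from) their
    smallest member id.  An undefined pairwise entry among ``ids`` is an
    error naming the offending pair.
    """
    if ids is None:
        ids = self_ids = matrix.ids
    else:
        self_ids = list(ids)
    idx = [matrix.index(i) for i in self_ids]
    sub = matrix.d[np.ix_(idx, idx)]
    bad = np.argwhere(np.isnan(sub))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"undefined distance between {self_ids[i]!r} and {self_ids[j]!r}"
        )
    # union-find over pairs below the cutoff
    parent = list(range(len(self_ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(self_ids)):
        for j in range(i + 1, len(self_ids)):
            if sub[i, j] < cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[str]] = {}
    for k, sid in enumerate(self_ids):
        groups.setdefault(find(k), []).append(sid)
    clusters = [sorted(g) for g in groups.values()]
    clusters.sort(key=lambda g: g[0])
    return clusters


def detect_shared_haplotypes(
    matrix: DistanceMatrix, species_of: Mapping[str, str]
) -> list[tuple[str, str, str, str]]:
    """Cross-species pairs at distance exactly zero.

    Returns sorted ``(id1, species1, id2, species2)`` tuples with
    ``id1 < id2``; same-species identical pairs are not reported.
    """
    pairs = []
    ids = matrix.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if matrix.d[i, j] == 0.0:
                a, b = ids[i], ids[j]
                if species_of[a] != species_of[b]:
                    a, b = min(a, b), max(a, b)
                    pairs.append((a, species_of[a], b, species_of[b]))
    return sorted(pairs)
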