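"""Similarity-aware dataset partitioning and train/test independence cleaning.

Cross-validation folds for sequence models leak badly if near-identical
guides straddle the train/validation boundary.  Partitions are therefore
built so that any two 30mers differing by at most ``max_mismatch``
(default 4) nucleotides — one-hot Hamming distance <= 8 — always share a
partition: the similarity relation is closed transitively (union-find)
and whole clusters are placed together.  Remaining singletons are dealt
out stratified by efficiency (below the 25th percentile, 25th-75th,
above the 75th) so every partition sees the full activity range, until
the near-equal (+-1) target sizes are met.

Independent test sets are additionally cleaned by removing every test
guide whose 20-nt spacer is within 3 mismatches (one-hot Hamming <= 6)
of any training spacer; partitioning uses the 30mer, test cleaning the
spacer alone, because context conventions differ between studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CODE = {c: i for i, c in enumerate("ACGT")}


def _encode(seqs: list[str]) -> np.ndarray:
    arr = np.empty((len(seqs), len(seqs[0]) if seqs else 0), dtype=np.uint8)
    for i, s in enumerate(seqs):
        arr[i] = [_CODE[c] for c in s]
    return arr


def _mismatch_pairs(arr: np.ndarray, max_mm: int, block: int = 256):
    """Yield (i, j) index pairs with <= max_mm mismatching positions."""
    n = arr.shape[0]
    for s in range(0, n, block):
        a = arr[s:s + block]
        for t in range(s, n, block):
            b = arr[t:t + block]
            mm = (a[:, None, :] != b[None, :, :]).sum(axis=2)
            ii, jj = np.nonzero(mm <= max_mm)
            for i, j in zip(ii + s, jj + t):
                if i < j:
                    yield int(i), int(j)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def similarity_clusters(mer30s: list[str], max_mismatch: int = 4) -> tuple[list[list[int]], list[int]]:
    """Transitive closure of the <= ``max_mismatch``-difference relation.

    Returns ``(clusters, singletons)`` as index lists into ``mer30s``;
    clusters have >= 2 members.  Duplicate 30mers are an error — they
    must be averaged upstream.
    """
    if len(set(mer30s)) != len(mer30s):
        raise ValueError("duplicate 30mers; deduplicate before clustering")
    arr = _encode(list(mer30s))
    uf = _UnionFind(len(mer30s))
    for i, j in _mismatch_pairs(arr, max_mismatch):
        uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(mer30s)):
        groups.setdefault(uf.find(i), []).append(i)
    clusters = [g for g in groups.values() if len(g) > 1]
    singletons = [g[0] for g in groups.values() if len(g) == 1]
    return clusters, singletons


@dataclass
class PartitionAssignment:
    """guide index -> partition (1..k) with cluster provenance."""

    partition: np.ndarray
    cluster_id: np.ndarray
    k: int
    seed: int
    reserved_partition: int | None = None
    warnings: list[str] = field(default_factory=list)

    def indices(self, part: int) -> np.ndarray:
        return np.nonzero(self.partition == part)[0]

    def to_frame(self, guide_ids=None) -> pd.DataFrame:
        df = pd.DataFrame({"partition": self.partition, "cluster_id": self.cluster_id})
        if guide_ids is not None:
            df.insert(0, "guide_id", list(guide_ids))
        return df


def _stratify(eff: np.ndarray) -> np.ndarray:
    """Stratum per value: 0 inefficient (<= 25p), 1 medium, 2 (> 75p)."""
    q25, q75 = np.percentile(eff, [25, 75])
    return np.where(eff <= q25, 0, np.where(eff <= q75, 1, 2))


def make_partitions(mer30s: list[str], efficiencies, k: int = 6, seed: int = 0,
                    max_mismatch: int = 4,
                    reserved_test_ids=None,
                    reserved_partition: int | None = None) -> PartitionAssignment:
    """Split a dataset into ``k`` near-equal, similarity-closed partitions.

    ``reserved_test_ids`` (indices into ``mer30s``) pins a group — plus
    everything recursively similar to it — to ``reserved_partition``
    (default: partition ``k``) before anything else is placed, so that
    partition can serve as an internal independent test set.  Similarity
    clusters are then placed whole, uniformly at random among partitions
    with enough remaining capacity; singleton guides are dealt balanced
    across the three efficiency strata until target sizes (+-1) are met.
    """
    n = len(mer30s)
    if n < k:
        raise ValueError(f"need at least k={k} guides, got {n}")
    eff = np.asarray(efficiencies, dtype=float)
    rng = np.random.default_rng(seed)
    clusters, singleton_idx = similarity_clusters(mer30s, max_mismatch)

    cluster_id = np.full(n, -1, dtype=np.int64)
    for cid, members in enumerate(clusters):
        for m in members:
            cluster_id[m] = cid

    base = n // k
    capacity = np.array([base + (1 if p < n % k else 0) for p in range(k)], dtype=np.int64)
    partition = np.zeros(n, dtype=np.int64)
    warnings: list[str] = []

    # --- reserved initial group, pinned to the designated test partition
    if reserved_partition is None:
        reserved_partition = k
    rp = reserved_partition - 1
    placed_clusters: set[int] = set()
    if reserved_test_ids is not None and len(reserved_test_ids):
        group = set(int(i) for i in reserved_test_ids)
        for i in list(group):
            if cluster_id[i] >= 0:
                group.update(clusters[cluster_id[i]])
                placed_clusters.add(int(cluster_id[i]))
        for i in group:
            partition[i] = reserved_partition
        capacity[rp] -= len(group)
        if capacity[rp] < 0:
            warnings.append(f"reserved group of {len(group)} exceeds partition target size")
            capacity[rp] = 0
        singleton_idx = [i for i in singleton_idx if i not in group]

    # --- whole clusters, uniformly among partitions with room
    order = rng.permutation(len(clusters))
    for cid in order:
        if cid in placed_clusters:
            continue
        members = clusters[cid]
        fits = np.nonzero(capacity >= len(members))[0]
        if fits.size:
            p = int(rng.choice(fits))
        else:
            p = int(np.argmax(capacity))
            warnings.append(f"cluster of {len(members)} exceeds every remaining capacity")
            logger.warning(warnings[-1])
        for m in members:
            partition[m] = p + 1
        capacity[p] = max(0, capacity[p] - len(members))

    # --- singletons: efficiency-stratified balanced dealing
    singles = np.array(singleton_idx, dtype=np.int64)
    if singles.size:
        strata = _stratify(eff[singles])
        total_cap = capacity.sum()
        # per-stratum quotas proportional to remaining capacity (largest
        # remainder), then a fix-up so each partition is filled exactly.
        quota = np.zeros((k, 3), dtype=np.int64)
        for s in range(3):
            ns = int(np.count_nonzero(strata == s))
            if total_cap > 0:
                exact = capacity * ns / total_cap
                quota[:, s] = np.floor(exact).astype(np.int64)
                rem = ns - quota[:, s].sum()
                if rem > 0:
                    frac = exact - np.floor(exact)
                    for p in np.argsort(-frac)[:rem]:
                        quota[p, s] += 1
        # fix column sums to the exact capacities (move surplus between
        # partitions within the largest stratum)
        diff = quota.sum(axis=1) - capacity
        while diff.max(initial=0) > 0:
            src = int(np.argmax(diff))
            dst = int(np.argmin(diff))
            s = int(np.argmax(quota[src]))
            quota[src, s] -= 1
            quota[dst, s] += 1
            diff = quota.sum(axis=1) - capacity
        for s in range(3):
            members = singles[strata == s]
            members = members[rng.permutation(members.size)]
            pos = 0
            for p in range(k):
                take = quota[p, s]
                for m in members[pos:pos + take]:
                    partition[m] = p + 1
                pos += take
    return PartitionAssignment(partition, cluster_id, k=k, seed=seed,
                               reserved_partition=reserved_partition, warnings=warnings)


def clean_test_set(test_spacers: list[str], train_spacer_sets,
                   max_mismatch: int = 3) -> tuple[list[int], list[int]]:
    """Indices of test guides kept/removed by train-set independence.

    A test guide is removed when its 20-nt spacer is within
    ``max_mismatch`` substitutions (one-hot Hamming <= 2*max_mismatch)
    of any spacer in any of the provided training sets.
    """
    if not test_spacers:
        return [], []
    test_arr = _encode(list(test_spacers))
    removed = np.zeros(len(test_spacers), dtype=bool)
    for train in train_spacer_sets:
        train = list(train)
        if not train:
            continue
        train_arr = _encode(train)
        for s in range(0, len(train), 256):
            blk = train_arr[s:s + 256]
            mm = (test_arr[:, None, :] != blk[None, :, :]).sum(axis=2)
            removed |= (mm <= max_mismatch).any(axis=1)
    kept = [i for i in range(len(test_spacers)) if not removed[i]]
    gone = [i for i in range(len(test_spacers)) if removed[i]]
    return kept, gone


def cross_partition_similar_pairs(mer30s: list[str], assignment: PartitionAssignment,
                                  max_mismatch: int = 4) -> int:
    """Brute-force count of similar pairs split across partitions (should be 0)."""
    arr = _encode(list(mer30s))
    bad = 0
    for i, j in _mismatch_pairs(arr, max_mismatch):
        if assignment.partition[i] != assignment.partition[j]:
            bad += 1
    return bad
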