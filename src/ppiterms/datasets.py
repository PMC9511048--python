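"""Negative-pair sampling and balanced-dataset construction.

Positives are the experimentally supported interactions.  Any other unordered
pair of the protein universe is a candidate negative.  Because negatives
vastly outnumber positives, the negative pool is split into K roughly equal
disjoint subsets, and each subset is combined with the full positive set to
form one balanced dataset.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

from ._rng import stream
from .types import BalancedDataset, InteractionTable, Pair, canonical_pair

logger = logging.getLogger(__name__)


def count_all_pairs(n_proteins: int) -> int:
    """Number of unordered, non-self pairs: C(n, 2)."""
    if n_proteins < 2:
        raise ValueError(f"need at least 2 proteins, got {n_proteins}")
    return n_proteins * (n_proteins - 1) // 2


def sample_negatives(
    proteins: Sequence[str],
    positives: InteractionTable,
    count: int | str,
    seed: int,
) -> list[Pair]:
    """Sample unordered non-self pairs that are not positive interactions.

    ``count="all"`` enumerates the exact complement (desk scale only); an
    integer draws a uniform sample without replacement by rejection against
    the positive set.  Deterministic given ``seed``.
    """
    ids = sorted(set(proteins))
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 proteins to form pairs")
    pos = positives.pair_set()
    feasible = count_all_pairs(n) - len(pos)

    if count == "all":
        out = [
            canonical_pair(a, b)
            for a, b in itertools.combinations(ids, 2)
            if (a, b) not in pos
        ]
        return out

    count = int(count)
    if count > feasible:
        raise ValueError(
            f"requested {count} negatives but only {feasible} non-positive pairs exist"
        )
    rng = stream(seed, "sample_negatives")
    chosen: set[Pair] = set()
    out: list[Pair] = []
    # rejection sampling against a hash set; avoids materializing C(n,2) pairs
    while len(out) < count:
        k = max(64, 2 * (count - len(out)))
        ii = rng.integers(0, n, size=k)
        jj = rng.integers(0, n, size=k)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            p = canonical_pair(ids[i], ids[j])
            if p in pos or p in chosen:
                continue
            chosen.add(p)
            out.append(p)
            if len(out) == count:
                break
    return out


def num_subsets(n_negatives: int, n_positives: int) -> int:
    """How many balanced datasets the negative pool supports: floor(neg/pos)."""
    if n_positives <= 0:
        raise ValueError("number of positives must be positive")
    if n_negatives <= 0:
        raise ValueError("number of negatives must be positive")
    return max(1, n_negatives // n_positives)


def partition(negatives: Sequence[Pair], k: int, seed: int) -> list[list[Pair]]:
    """Randomly split the pool into K subsets whose sizes differ by at most 1.

    The remainder is spread over the first subsets, so with 10 pairs and K=3
    the sizes are (4, 3, 3).  Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(negatives):
        raise ValueError(f"k={k} exceeds pool size {len(negatives)}")
    rng = stream(seed, "partition")
    order = rng.permutation(len(negatives))
    shuffled = [negatives[i] for i in order]
    base, rem = divmod(len(shuffled), k)
    out: list[list[Pair]] = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        out.append(shuffled[start : start + size])
        start += size
    return out


def build_datasets(
    positives: InteractionTable | Sequence[Pair],
    negative_subsets: Sequence[Sequence[Pair]],
) -> list[BalancedDataset]:
    """One balanced dataset per negative subset, each carrying all positives."""
    pos_pairs = (
        list(positives.pairs)
        if isinstance(positives, InteractionTable)
        else list(positives)
    )
    pos_set = set(pos_pairs)
    seen: set[Pair] = set()
    for subset in negative_subsets:
        s = set(subset)
        if s & pos_set:
            raise ValueError("negative subset overlaps the positive set")
        if s & seen:
            raise ValueError("negative subsets are not pairwise disjoint")
        seen |= s
    return [
        BalancedDataset(
            dataset_id=i + 1,
            positive_pairs=pos_pairs,
            negative_pairs=list(subset),
        )
        for i, subset in enumerate(negative_subsets)
    ]
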