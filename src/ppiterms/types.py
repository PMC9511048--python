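"""Core domain types shared across the pipeline.

The pipeline studies which functional annotations (GO terms and KEGG
pathways) are associated with protein-protein interactions.  Every protein
carries a sparse binary annotation profile; an interaction (an unordered
protein pair) is encoded order-invariantly as, per term, the sum and the
absolute difference of the two proteins' indicator bits.  Downstream stages
(relevance filtering, ranking, consensus scoring) all index features through
the catalog defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import scipy.sparse as sp

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Unordered pair stored lexicographically; orientation carries no meaning."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class AnnotationCatalog:
    """The ordered universes of GO terms (length n) and KEGG pathways (length m).

    Term order is fixed for the lifetime of a run: every annotation vector and
    every pair feature vector is indexed through this catalog.
    """

    go_terms: tuple[str, ...]
    kegg_pathways: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.go_terms)) != len(self.go_terms):
            raise ValueError("duplicate GO term identifiers in catalog")
        if len(set(self.kegg_pathways)) != len(self.kegg_pathways):
            raise ValueError("duplicate KEGG pathway identifiers in catalog")
        if set(self.go_terms) & set(self.kegg_pathways):
            raise ValueError("GO and KEGG identifier lists must be disjoint")
        if not self.go_terms and not self.kegg_pathways:
            raise ValueError("catalog needs at least one annotation channel")

    @property
    def n(self) -> int:
        return len(self.go_terms)

    @property
    def m(self) -> int:
        return len(self.kegg_pathways)

    @property
    def n_features(self) -> int:
        """Total pair-feature count: two channels (sum, |diff|) per term."""
        return 2 * (self.n + self.m)

    def go_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.go_terms)}

    def kegg_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.kegg_pathways)}


@dataclass(frozen=True)
class ProteinProfile:
    """A protein's annotations as index sets into the catalog.

    A protein annotated by neither channel is invalid: such proteins carry no
    usable functional information and are discarded upstream.
    """

    protein_id: str
    go_set: frozenset[int]
    kegg_set: frozenset[int]

    def __post_init__(self) -> None:
        if not self.go_set and not self.kegg_set:
            raise ValueError(
                f"protein {self.protein_id!r} has no GO term and no KEGG pathway"
            )

    def validate(self, catalog: AnnotationCatalog) -> None:
        if self.go_set and max(self.go_set) >= catalog.n:
            raise IndexError(f"GO index out of range for protein {self.protein_id!r}")
        if self.kegg_set and max(self.kegg_set) >= catalog.m:
            raise IndexError(f"KEGG index out of range for protein {self.protein_id!r}")


@dataclass
class InteractionTable:
    """Canonicalized unordered protein pairs with experimental scores."""

    pairs: list[Pair]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.pairs) != len(self.scores):
            raise ValueError("pairs and scores length mismatch")
        seen: set[Pair] = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair ({a},{b}) in interaction table")
            p = canonical_pair(a, b)
            if p != (a, b):
                raise ValueError(f"pair ({a},{b}) not canonicalized")
            if p in seen:
                raise ValueError(f"duplicate pair {p}")
            seen.add(p)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return out

    def pair_set(self) -> frozenset[Pair]:
        return frozenset(self.pairs)


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one pair-feature channel.

    ``feature_id`` indexes the fixed ordering: all GO terms in catalog order,
    sum channel before |difference| channel per term, then all KEGG pathways
    likewise.
    """

    feature_id: int
    term_id: str
    channel: str  # "GO" | "KEGG"
    combinator: str  # "sum" | "absdiff"

    def __post_init__(self) -> None:
        if self.channel not in ("GO", "KEGG"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.combinator not in ("sum", "absdiff"):
            raise ValueError(f"unknown combinator {self.combinator!r}")

    @property
    def name(self) -> str:
        """Canonical machine name, e.g. ``sum:GO:0031224``."""
        return f"{self.combinator}:{self.term_id}"

    @property
    def display_name(self) -> str:
        """Report-style name, e.g. ``hsa04060_1 + hsa04060_2`` or
        ``abs (GO:0031224_1-GO:0031224_2)``."""
        if self.combinator == "sum":
            return f"{self.term_id}_1 + {self.term_id}_2"
        return f"abs ({self.term_id}_1-{self.term_id}_2)"


@dataclass
class BalancedDataset:
    """All positive pairs plus one disjoint subset of sampled negatives."""

    dataset_id: int
    positive_pairs: list[Pair]
    negative_pairs: list[Pair]

    def __post_init__(self) -> None:
        if set(self.positive_pairs) & set(self.negative_pairs):
            raise ValueError(
                f"dataset {self.dataset_id}: positive and negative pairs overlap"
            )

    @property
    def pairs(self) -> list[Pair]:
        return list(self.positive_pairs) + list(self.negative_pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate(
            [
                np.ones(len(self.positive_pairs), dtype=np.int8),
                np.zeros(len(self.negative_pairs), dtype=np.int8),
            ]
        )


@dataclass
class PairFeatureMatrix:
    """Sparse pair-by-feature matrix for one balanced dataset.

    Values are small integers: sum channels take {0,1,2}, |difference|
    channels take {0,1}; per term the (sum, absdiff) pair is always one of
    (0,0), (1,1), (2,0).
    """

    dataset_id: int
    X: sp.csr_matrix
    labels: np.ndarray
    descriptors: list[FeatureDescriptor]
    pairs: list[Pair] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.X.shape[0] != len(self.labels):
            raise ValueError("row count and label count differ")
        if self.X.shape[1] != len(self.descriptors):
            raise ValueError("column count and descriptor count differ")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class FilterResult:
    """Outcome of the shadow-feature relevance filter on one dataset."""

    dataset_id: int
    selected: frozenset[int]
    n_iterations: int
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected = frozenset(int(f) for f in self.selected)


@dataclass
class RankedList:
    """One ranking algorithm's ordered feature list for one balanced dataset.

    Rank 1 is the most important feature; a feature absent from the list has
    implicit rank 0 in the consensus bookkeeping.
    """

    dataset_id: int
    algorithm: str
    feature_ids: list[int]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.scores):
            raise ValueError("feature_ids and scores length mismatch")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate features in ranked list")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def rank_of(self, feature_id: int) -> int:
        """1-based rank, or 0 if the list does not contain the feature."""
        try:
            return self.feature_ids.index(feature_id) + 1
        except ValueError:
            return 0


@dataclass(frozen=True)
class ConsensusRecord:
    """Per-feature consensus bookkeeping across K per-dataset lists.

    ``score = M_f / W_f`` where ``M_f`` is the mean rank over the ``N_f``
    lists containing the feature and ``W_f = N_f / K``.  Smaller score means
    more important.
    """

    feature_id: int
    n_f: int
    m_f: float
    w_f: float
    score: float


@dataclass
class VennPartition:
    """Membership classes of three top-N feature sets."""

    triple: frozenset[int]
    double: dict[int, frozenset[str]]  # feature -> the two algorithm labels
    single: dict[int, str]  # feature -> the one algorithm label

    def conservation(self) -> int:
        """3|triple| + 2|double| + |single|; equals the summed top-N sizes."""
        return 3 * len(self.triple) + 2 * len(self.double) + len(self.single)


def profiles_by_id(profiles: Iterable[ProteinProfile]) -> dict[str, ProteinProfile]:
    return {p.protein_id: p for p in profiles}
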