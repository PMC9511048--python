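"""Rank aggregation across balanced datasets and the top-N Venn partition.

For one ranking algorithm run on K balanced datasets there are K ranked
feature lists F_1..F_K.  A feature f appearing in N(f) of them, at ranks
R_i(f) (R_i(f)=0 when absent), gets

    M(f) = sum_i R_i(f) / N(f)      (mean rank over the lists containing it)
    W(f) = N(f) / K                 (fraction of datasets selecting it)
    importance score(f) = M(f) / W(f)

Smaller score = more important: a feature ranked well and selected often
scores low.  The three algorithms' integrated lists are then cut at top N and
intersected to classify features as found by three, two, or one algorithm.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import (
    ConsensusRecord,
    FeatureDescriptor,
    RankedList,
    VennPartition,
)

logger = logging.getLogger(__name__)


def integrate(lists: Sequence[RankedList], k: int | None = None) -> list[ConsensusRecord]:
    """Collapse K per-dataset ranked lists into one consensus ordering.

    ``k`` is the number of balanced datasets (defaults to ``len(lists)``); it
    may exceed ``len(lists)`` when some datasets produced no ranked features.
    Records are sorted by ascending score, ties by ascending feature id.
    """
    if not lists:
        raise ValueError("no ranked lists to integrate")
    algorithms = {l.algorithm for l in lists}
    if len(algorithms) != 1:
        raise ValueError(f"lists mix algorithms: {sorted(algorithms)}")
    if k is None:
        k = len(lists)
    if k < len(lists):
        raise ValueError("k cannot be smaller than the number of lists")

    rank_sum: dict[int, int] = defaultdict(int)
    n_f: dict[int, int] = defaultdict(int)
    for lst in lists:
        for rank, fid in enumerate(lst.feature_ids, start=1):
            rank_sum[fid] += rank
            n_f[fid] += 1

    records = []
    for fid in rank_sum:
        nf = n_f[fid]
        mf = rank_sum[fid] / nf
        wf = nf / k
        records.append(
            ConsensusRecord(feature_id=fid, n_f=nf, m_f=mf, w_f=wf, score=mf / wf)
        )
    records.sort(key=lambda r: (r.score, r.feature_id))
    return records


def top_n(consensus: Sequence[ConsensusRecord], n: int = 100) -> list[int]:
    """First n feature ids of the consensus ordering (all of them if fewer)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(consensus):
        warnings.warn(
            f"requested top {n} but only {len(consensus)} features are ranked"
        )
    return [r.feature_id for r in consensus[:n]]


def venn(tops: Mapping[str, Iterable[int]] | Sequence[tuple[str, Iterable[int]]]) -> VennPartition:
    """Partition three labeled top-N sets by how many algorithms found each feature."""
    items = list(tops.items()) if isinstance(tops, Mapping) else list(tops)
    labels = [lab for lab, _ in items]
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate algorithm labels: {labels}")
    if len(items) != 3:
        raise ValueError(f"expected exactly 3 labeled sets, got {len(items)}")
    sets = {lab: set(int(f) for f in feats) for lab, feats in items}

    membership: dict[int, list[str]] = defaultdict(list)
    for lab in labels:
        for f in sets[lab]:
            membership[f].append(lab)

    triple = frozenset(f for f, labs in membership.items() if len(labs) == 3)
    double = {
        f: frozenset(labs) for f, labs in membership.items() if len(labs) == 2
    }
    single = {f: labs[0] for f, labs in membership.items() if len(labs) == 1}
    return VennPartition(triple=triple, double=double, single=single)


def render_report(
    consensus: Mapping[str, Sequence[ConsensusRecord]],
    venn_partition: VennPartition,
    descriptors: Sequence[FeatureDescriptor],
    top: int = 100,
    boruta_counts: Mapping[int, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Tabular report data.

    Returns three frames: per-algorithm GO-vs-KEGG composition of the top-N,
    the Venn membership table with report-style feature names, and the
    per-dataset filter-selection counts (violin-plot data).
    """
    desc_by_id = {d.feature_id: d for d in descriptors}

    rows = []
    for alg in sorted(consensus):
        ids = top_n(consensus[alg], top) if consensus[alg] else []
        n_go = sum(1 for f in ids if desc_by_id[f].channel == "GO")
        n_kegg = sum(1 for f in ids if desc_by_id[f].channel == "KEGG")
        rows.append({"algorithm": alg, "go": n_go, "kegg": n_kegg, "total": len(ids)})
    channel_counts = pd.DataFrame(rows, columns=["algorithm", "go", "kegg", "total"])

    vrows = []
    for f in sorted(venn_partition.triple):
        vrows.append((f, 3, ",".join(sorted(consensus))))
    for f in sorted(venn_partition.double):
        vrows.append((f, 2, ",".join(sorted(venn_partition.double[f]))))
    for f in sorted(venn_partition.single):
        vrows.append((f, 1, venn_partition.single[f]))
    venn_table = pd.DataFrame(
        [
            {
                "feature_id": f,
                "feature": desc_by_id[f].name,
                "display_name": desc_by_id[f].display_name,
                "n_algorithms": n,
                "algorithms": labs,
            }
            for f, n, labs in vrows
        ],
        columns=["feature_id", "feature", "display_name", "n_algorithms", "algorithms"],
    )

    if boruta_counts:
        filter_counts = pd.DataFrame(
            sorted(boruta_counts.items()), columns=["dataset_id", "n_selected"]
        )
    else:
        filter_counts = pd.DataFrame(columns=["dataset_id", "n_selected"])

    return {
        "channel_counts": channel_counts,
        "venn_table": venn_table,
        "filter_counts": filter_counts,
    }
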