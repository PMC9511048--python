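"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from ppiterms import AnnotationCatalog, ProteinProfile


# ---------------------------------------------------------------------------
# independent mutual-information / mRMR oracle (plain loops + Counter; no
# shared code with ppiterms.rankers)
# ---------------------------------------------------------------------------

def mi_oracle(x, y) -> float:
    """Plug-in mutual information in nats, computed with dictionaries."""
    x = list(x)
    y = list(y)
    n = len(x)
    cx = Counter(x)
    cy = Counter(y)
    cxy = Counter(zip(x, y))
    total = 0.0
    for (a, b), nab in cxy.items():
        pab = nab / n
        total += pab * math.log(pab / ((cx[a] / n) * (cy[b] / n)))
    return total


def mrmr_oracle(X, y, top_k=None) -> list[int]:
    """Brute-force greedy max-relevance min-redundancy (difference criterion).

    Returns column indices in pick order; ties broken by smallest index.
    Remaining columns are appended in ascending index order.
    """
    X = np.asarray(X)
    y = list(np.asarray(y).ravel())
    k = X.shape[1]
    if top_k is None:
        top_k = k
    cols = [list(X[:, j]) for j in range(k)]
    relevance = [mi_oracle(cols[j], y) for j in range(k)]
    selected: list[int] = []
    remaining = list(range(k))
    while remaining and len(selected) < top_k:
        vals = {}
        for j in remaining:
            if selected:
                red = sum(mi_oracle(cols[j], cols[s]) for s in selected) / len(selected)
            else:
                red = 0.0
            vals[j] = relevance[j] - red
        best_val = max(vals.values())
        # criterion values within 1e-9 tie; the smallest index wins
        best_j = min(j for j, v in vals.items() if v >= best_val - 1e-9)
        selected.append(best_j)
        remaining.remove(best_j)
    return selected + remaining


@pytest.fixture
def tiny_catalog() -> AnnotationCatalog:
    return AnnotationCatalog(
        go_terms=("GO:0000001", "GO:0000002", "GO:0000003"),
        kegg_pathways=("hsa00001", "hsa00002"),
    )


@pytest.fixture
def tiny_profiles(tiny_catalog) -> dict[str, ProteinProfile]:
    return {
        "A": ProteinProfile("A", frozenset({0}), frozenset({0})),
        "B": ProteinProfile("B", frozenset({0, 1}), frozenset()),
        "C": ProteinProfile("C", frozenset(), frozenset({1})),
        "D": ProteinProfile("D", frozenset({2}), frozenset({0, 1})),
    }


def write_tsv(path, rows, header=None):
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
    return path
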