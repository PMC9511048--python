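"""Order-invariant pair encoding.

A protein ``p`` is a pair of binary indicator vectors over the catalog:
``v_GO(p)[i] = 1`` iff the i-th GO term annotates ``p``, and likewise
``v_KEGG(p)`` over pathways.  An interacting pair (p1, p2) must be encoded
without orientation, so per term the two channels kept are the sum
``g_i(p1) + g_i(p2)`` (ternary: 0/1/2) and the absolute difference
``|g_i(p1) - g_i(p2)|`` (binary).  The full pair vector concatenates the GO
block then the KEGG block, sum before absdiff within each term, giving
2(n+m) features.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .types import (
    AnnotationCatalog,
    BalancedDataset,
    FeatureDescriptor,
    PairFeatureMatrix,
    ProteinProfile,
)


def build_descriptors(catalog: AnnotationCatalog) -> list[FeatureDescriptor]:
    """The fixed feature ordering: GO terms (sum, absdiff per term), then KEGG."""
    out: list[FeatureDescriptor] = []
    fid = 0
    for term in catalog.go_terms:
        out.append(FeatureDescriptor(fid, term, "GO", "sum"))
        out.append(FeatureDescriptor(fid + 1, term, "GO", "absdiff"))
        fid += 2
    for term in catalog.kegg_pathways:
        out.append(FeatureDescriptor(fid, term, "KEGG", "sum"))
        out.append(FeatureDescriptor(fid + 1, term, "KEGG", "absdiff"))
        fid += 2
    return out


def encode_protein(
    profile: ProteinProfile, catalog: AnnotationCatalog
) -> tuple[np.ndarray, np.ndarray]:
    """Binary annotation vectors (v_GO, v_KEGG) of lengths n and m."""
    profile.validate(catalog)
    v_go = np.zeros(catalog.n, dtype=np.int8)
    v_kegg = np.zeros(catalog.m, dtype=np.int8)
    if profile.go_set:
        v_go[sorted(profile.go_set)] = 1
    if profile.kegg_set:
        v_kegg[sorted(profile.kegg_set)] = 1
    return v_go, v_kegg


def encode_pair(
    p1: ProteinProfile, p2: ProteinProfile, catalog: AnnotationCatalog
) -> np.ndarray:
    """Dense pair vector of length 2(n+m); symmetric in its two arguments."""
    g1, k1 = encode_protein(p1, catalog)
    g2, k2 = encode_protein(p2, catalog)
    vec = np.empty(catalog.n_features, dtype=np.int8)
    vec[0 : 2 * catalog.n : 2] = g1 + g2
    vec[1 : 2 * catalog.n : 2] = np.abs(g1 - g2)
    off = 2 * catalog.n
    vec[off::2] = k1 + k2
    vec[off + 1 :: 2] = np.abs(k1 - k2)
    return vec


def _pair_entries(
    s1: frozenset[int], s2: frozenset[int], col_offset: int
) -> tuple[list[int], list[int]]:
    """Sparse (column, value) entries for one annotation channel of one pair."""
    cols: list[int] = []
    vals: list[int] = []
    both = s1 & s2
    either = s1 | s2
    for i in either:
        base = col_offset + 2 * i
        if i in both:
            cols.append(base)
            vals.append(2)
        else:
            cols.append(base)
            vals.append(1)
            cols.append(base + 1)
            vals.append(1)
    return cols, vals


def encode_dataset(
    ds: BalancedDataset,
    profiles: Mapping[str, ProteinProfile],
    catalog: AnnotationCatalog,
) -> PairFeatureMatrix:
    """Encode every pair of a balanced dataset as a sparse CSR matrix.

    Row order is positives in input order then negatives in input order.
    """
    pairs = ds.pairs
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    kegg_offset = 2 * catalog.n
    for r, (a, b) in enumerate(pairs):
        for pid in (a, b):
            if pid not in profiles:
                raise KeyError(f"no annotation profile for protein {pid!r}")
        pa, pb = profiles[a], profiles[b]
        c, v = _pair_entries(pa.go_set, pb.go_set, 0)
        rows.extend([r] * len(c))
        cols.extend(c)
        vals.extend(v)
        c, v = _pair_entries(pa.kegg_set, pb.kegg_set, kegg_offset)
        rows.extend([r] * len(c))
        cols.extend(c)
        vals.extend(v)
    X = sp.csr_matrix(
        (np.asarray(vals, dtype=np.int8), (rows, cols)),
        shape=(len(pairs), catalog.n_features),
    )
    return PairFeatureMatrix(
        dataset_id=ds.dataset_id,
        X=X,
        labels=ds.labels,
        descriptors=build_descriptors(catalog),
        pairs=pairs,
    )


def export_matrix_market(
    matrix: PairFeatureMatrix, mtx_path, rows_path=None, cols_path=None
) -> None:
    """Optional MatrixMarket export with sidecar TSVs for pairs and features."""
    import scipy.io as sio

    sio.mmwrite(str(mtx_path), matrix.X)
    if rows_path is not None:
        with open(rows_path, "w") as fh:
            fh.write("protein1\tprotein2\tlabel\n")
            for (a, b), lab in zip(matrix.pairs, matrix.labels):
                fh.write(f"{a}\t{b}\t{int(lab)}\n")
    if cols_path is not None:
        with open(cols_path, "w") as fh:
            fh.write("feature_id\tname\tterm\tchannel\tcombinator\tdisplay_name\n")
            for d in matrix.descriptors:
                fh.write(
                    f"{d.feature_id}\t{d.name}\t{d.term_id}\t{d.channel}"
                    f"\t{d.combinator}\t{d.display_name}\n"
                )
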