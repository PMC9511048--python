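"""Order-invariant pair encoding: channel values, ordering, sparsity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppiterms import (
    AnnotationCatalog,
    BalancedDataset,
    ProteinProfile,
    build_descriptors,
    encode_dataset,
    encode_pair,
    encode_protein,
)


class TestEncodeProtein:
    def test_indicator_placement(self):
        cat = AnnotationCatalog(("GO:1", "GO:2", "GO:3"), ("hsa1", "hsa2"))
        prof = ProteinProfile("p", frozenset({0}), frozenset())
        v_go, v_kegg = encode_protein(prof, cat)
        assert v_go.tolist() == [1, 0, 0]
        assert v_kegg.tolist() == [0, 0]

    def test_support_equals_annotation_sets(self):
        cat = AnnotationCatalog(("GO:1", "GO:2", "GO:3", "GO:4"), ("hsa1",))
        prof = ProteinProfile("p", frozenset({1, 3}), frozenset({0}))
        v_go, v_kegg = encode_protein(prof, cat)
        assert set(np.flatnonzero(v_go)) == prof.go_set
        assert set(np.flatnonzero(v_kegg)) == prof.kegg_set

    def test_out_of_range_index_rejected(self):
        cat = AnnotationCatalog(("GO:1",), ())
        prof = ProteinProfile("p", frozenset({5}), frozenset())
        with pytest.raises(IndexError):
            encode_protein(prof, cat)


class TestEncodePair:
    def test_sum_and_absdiff_channels(self):
        cat = AnnotationCatalog(("A", "B"), ())
        p1 = ProteinProfile("p1", frozenset({0}), frozenset())
        p2 = ProteinProfile("p2", frozenset({0, 1}), frozenset())
        assert encode_pair(p1, p2, cat).tolist() == [2, 0, 1, 1]

    def test_identical_proteins(self):
        cat = AnnotationCatalog(("A", "B", "C"), ())
        p = ProteinProfile("p", frozenset({0, 2}), frozenset())
        vec = encode_pair(p, p, cat)
        assert vec[1::2].tolist() == [0, 0, 0]  # all absdiff channels zero
        assert vec[::2].tolist() == [2, 0, 2]

    def test_exhaustive_channel_compatibility(self):
        """All 4 per-term annotation combinations give (sum, absdiff) in
        {(0,0), (1,1), (2,0)}."""
        cat = AnnotationCatalog(("T",), ("K",))
        seen = set()
        for a in (False, True):
            for b in (False, True):
                p1 = ProteinProfile("p1", frozenset({0} if a else set()), frozenset({0}))
                p2 = ProteinProfile("p2", frozenset({0} if b else set()), frozenset({0}))
                vec = encode_pair(p1, p2, cat)
                seen.add((int(vec[0]), int(vec[1])))
        assert seen == {(0, 0), (1, 1), (2, 0)}

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        go1=st.sets(st.integers(0, 5), max_size=6),
        go2=st.sets(st.integers(0, 5), max_size=6),
        k1=st.sets(st.integers(0, 1), max_size=2),
        k2=st.sets(st.integers(0, 1), max_size=2),
    )
    def test_order_invariance(self, go1, go2, k1, k2):
        if not (go1 or k1) or not (go2 or k2):
            return  # empty profiles are invalid by construction
        cat = AnnotationCatalog(tuple(f"GO:{i}" for i in range(6)), ("hsa1", "hsa2"))
        p1 = ProteinProfile("p1", frozenset(go1), frozenset(k1))
        p2 = ProteinProfile("p2", frozenset(go2), frozenset(k2))
        assert np.array_equal(encode_pair(p1, p2, cat), encode_pair(p2, p1, cat))


class TestDescriptors:
    def test_ordering_and_count(self):
        cat = AnnotationCatalog(("GO:2", "GO:5"), ("hsa1",))
        descs = build_descriptors(cat)
        assert len(descs) == cat.n_features == 6
        assert [(d.term_id, d.combinator) for d in descs] == [
            ("GO:2", "sum"), ("GO:2", "absdiff"),
            ("GO:5", "sum"), ("GO:5", "absdiff"),
            ("hsa1", "sum"), ("hsa1", "absdiff"),
        ]

    def test_display_names_report_style(self):
        cat = AnnotationCatalog(("GO:0031224",), ("hsa04060",))
        descs = {(d.term_id, d.combinator): d for d in build_descriptors(cat)}
        assert descs[("hsa04060", "sum")].display_name == "hsa04060_1 + hsa04060_2"
        assert (
            descs[("GO:0031224", "absdiff")].display_name
            == "abs (GO:0031224_1-GO:0031224_2)"
        )


class TestEncodeDataset:
    def test_dimensions(self, tiny_catalog, tiny_profiles):
        ds = BalancedDataset(1, [("A", "B"), ("A", "C")], [("B", "C")])
        mat = encode_dataset(ds, tiny_profiles, tiny_catalog)
        assert mat.X.shape == (3, 2 * (3 + 2))

    def test_disjoint_singletons_give_four_nonzeros(self):
        cat = AnnotationCatalog(("GO:1", "GO:2"), ())
        profiles = {
            "A": ProteinProfile("A", frozenset({0}), frozenset()),
            "B": ProteinProfile("B", frozenset({1}), frozenset()),
        }
        ds = BalancedDataset(1, [("A", "B")], [])
        mat = encode_dataset(ds, profiles, cat)
        assert mat.X.nnz == 4
        assert mat.X.toarray().tolist() == [[1, 1, 1, 1]]

    def test_row_order_positives_then_negatives(self, tiny_catalog, tiny_profiles):
        ds = BalancedDataset(1, [("A", "B")], [("C", "D")])
        mat = encode_dataset(ds, tiny_profiles, tiny_catalog)
        assert mat.pairs == [("A", "B"), ("C", "D")]
        assert mat.labels.tolist() == [1, 0]
        assert np.array_equal(
            mat.X[0].toarray().ravel(),
            encode_pair(tiny_profiles["A"], tiny_profiles["B"], tiny_catalog),
        )

    def test_missing_profile_names_protein(self, tiny_catalog, tiny_profiles):
        ds = BalancedDataset(1, [("A", "Z")], [])
        with pytest.raises(KeyError, match="Z"):
            encode_dataset(ds, tiny_profiles, tiny_catalog)

    def test_channel_compatibility_and_sparsity_on_random_data(self):
        rng = np.random.default_rng(0)
        n_terms = 8
        cat = AnnotationCatalog(tuple(f"GO:{i}" for i in range(n_terms)), ())
        profiles = {}
        for i in range(20):
            go = frozenset(int(j) for j in np.flatnonzero(rng.random(n_terms) < 0.4))
            if not go:
                go = frozenset({int(rng.integers(n_terms))})
            profiles[f"p{i}"] = ProteinProfile(f"p{i}", go, frozenset())
        pairs = [(f"p{i}", f"p{j}") for i in range(10) for j in range(i + 1, 12)]
        ds = BalancedDataset(1, pairs, [])
        mat = encode_dataset(ds, profiles, cat)
        dense = mat.X.toarray()
        sums, diffs = dense[:, ::2], dense[:, 1::2]
        for s, d in zip(sums.ravel(), diffs.ravel()):
            assert (s, d) in {(0, 0), (1, 1), (2, 0)}
        # nonzero count per row from the two profiles' index sets
        for r, (a, b) in enumerate(pairs):
            sa, sb = profiles[a].go_set, profiles[b].go_set
            expected = len(sa | sb) + len(sa ^ sb)
            assert np.count_nonzero(dense[r]) == expected
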