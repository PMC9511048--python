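"""The synthetic universe generator and ground-truth recovery metrics."""

import itertools

import numpy as np
import pytest

from ppiterms import (
    SyntheticConfig,
    SyntheticTruth,
    generate,
    rank_separation,
    recovery_rate,
)
from ppiterms._rng import stream


def _sharing_fraction(pairs, profiles_by_id, catalog, signal_terms):
    """Fraction of pairs sharing >=1 signal term (direct recount, no library code)."""
    gidx = {t: i for i, t in enumerate(catalog.go_terms)}
    kidx = {t: i for i, t in enumerate(catalog.kegg_pathways)}
    sig_go = {gidx[t] for t in signal_terms if t in gidx}
    sig_kegg = {kidx[t] for t in signal_terms if t in kidx}
    n_share = 0
    for a, b in pairs:
        pa, pb = profiles_by_id[a], profiles_by_id[b]
        if (pa.go_set & pb.go_set & sig_go) or (pa.kegg_set & pb.kegg_set & sig_kegg):
            n_share += 1
    return n_share / len(pairs)


class TestGenerate:
    def test_deterministic(self):
        cfg = SyntheticConfig(n_proteins=60, n_go=30, n_kegg=8, n_signal=4,
                              n_pos=100, seed=5)
        a = generate(cfg)
        b = generate(cfg)
        assert a[2].pairs == b[2].pairs
        assert a[3] == b[3]
        assert [(p.protein_id, p.go_set, p.kegg_set) for p in a[1]] == [
            (p.protein_id, p.go_set, p.kegg_set) for p in b[1]
        ]

    def test_every_protein_annotated(self):
        cfg = SyntheticConfig(n_proteins=100, n_go=40, n_kegg=5, n_signal=3,
                              base_prevalence=0.02, n_pos=200, seed=2)
        _, profiles, _, _ = generate(cfg)
        assert len(profiles) == 100
        for p in profiles:
            assert p.go_set or p.kegg_set

    def test_signal_spans_both_channels(self):
        cfg = SyntheticConfig(n_proteins=60, n_go=40, n_kegg=10, n_signal=5,
                              n_pos=100, seed=1)
        _, _, _, truth = generate(cfg)
        assert any(t.startswith("GO:") for t in truth.signal_terms)
        assert any(t.startswith("hsa") for t in truth.signal_terms)
        assert len(truth.signal_terms) == 5
        assert len(truth.signal_features) == 10

    def test_null_enrichment_matches_uniform_sharing(self):
        """enrichment=1 plants nothing: positives share signal terms about as
        often as uniformly drawn pairs."""
        cfg = SyntheticConfig(n_proteins=300, n_go=100, n_kegg=20, n_signal=8,
                              n_pos=1500, enrichment=1.0, seed=7)
        catalog, profiles, table, truth = generate(cfg)
        pmap = {p.protein_id: p for p in profiles}
        obs = _sharing_fraction(table.pairs, pmap, catalog, truth.signal_terms)

        rng = stream(123, "uniform_oracle")
        ids = sorted(pmap)
        uni = []
        while len(uni) < 1500:
            i, j = rng.integers(0, len(ids), size=2)
            if i != j:
                uni.append((ids[i], ids[j]))
        exp = _sharing_fraction(uni, pmap, catalog, truth.signal_terms)
        se = np.sqrt(exp * (1 - exp) / 1500)
        assert abs(obs - exp) < 5 * se + 1e-9

    def test_enriched_positives_share_more_than_uniform(self):
        """The stated planted-signal condition: enrichment 20 makes positives'
        signal sharing exceed that of a same-size uniform resample."""
        cfg = SyntheticConfig(n_proteins=500, n_go=200, n_kegg=30, n_signal=10,
                              enrichment=20.0, n_pos=2000, seed=1)
        catalog, profiles, table, truth = generate(cfg)
        pmap = {p.protein_id: p for p in profiles}
        obs = _sharing_fraction(table.pairs, pmap, catalog, truth.signal_terms)

        rng = stream(99, "uniform_oracle")
        ids = sorted(pmap)
        uni = []
        while len(uni) < 2000:
            i, j = rng.integers(0, len(ids), size=2)
            if i != j:
                uni.append((ids[i], ids[j]))
        exp = _sharing_fraction(uni, pmap, catalog, truth.signal_terms)
        assert obs > exp

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_proteins=5, n_pos=100).validate()


class TestRecoveryRate:
    def _truth(self):
        return SyntheticTruth.from_terms([f"GO:{i}" for i in range(10)])

    def test_all_signal_first(self):
        truth = self._truth()
        features = [f"sum:GO:{i}" for i in range(10)]
        assert recovery_rate(truth, features, 10) == 1.0

    def test_no_signal_features(self):
        truth = self._truth()
        features = [f"sum:GO:{i}" for i in range(100, 120)]
        assert recovery_rate(truth, features, 20) == 0.0

    def test_partial_coverage(self):
        truth = self._truth()
        # sum and absdiff of the same term count once
        features = [f"sum:GO:{i}" for i in range(7)] + ["absdiff:GO:0"]
        features += [f"sum:GO:{i}" for i in range(50, 60)]
        assert recovery_rate(truth, features, 8) == 0.7

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            recovery_rate(self._truth(), [], 5)


class TestRankSeparation:
    def test_signal_first_gives_negative_stat_small_p(self):
        truth = SyntheticTruth.from_terms([f"GO:{i}" for i in range(5)])
        universe = [f"sum:GO:{i}" for i in range(40)]
        ranked = universe[:5] + universe[5:]
        stat, p = rank_separation(truth, ranked, universe, n_perm=500, seed=0)
        assert stat < 0 and p < 0.05

    def test_random_order_is_null(self):
        truth = SyntheticTruth.from_terms([f"GO:{i}" for i in range(5)])
        universe = [f"sum:GO:{i}" for i in range(40)]
        rng = np.random.default_rng(3)
        ranked = [universe[i] for i in rng.permutation(40)]
        _, p = rank_separation(truth, ranked, universe, n_perm=500, seed=0)
        assert p > 0.05

    def test_needs_both_classes(self):
        truth = SyntheticTruth.from_terms(["GO:0"])
        with pytest.raises(ValueError):
            rank_separation(truth, ["sum:GO:0"], ["sum:GO:0"], n_perm=10)
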