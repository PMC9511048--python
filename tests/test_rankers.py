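"""The three feature-ranking schemes and their deterministic contracts."""

import numpy as np
import pytest

from ppiterms import gbdt_rank, lasso_rank, mrmr_rank, mutual_information

from conftest import mi_oracle, mrmr_oracle


def _labelled_matrix(rng, n=200, k=8):
    """Random {0,1,2} matrix whose column 0 equals the label."""
    y = rng.integers(0, 2, size=n)
    X = rng.integers(0, 3, size=(n, k))
    X[:, 0] = y
    return X, y


class TestLassoRank:
    def test_perfect_column_ranks_first(self):
        rng = np.random.default_rng(1)
        X, y = _labelled_matrix(rng)
        ranked = lasso_rank(X, y, alpha=0.001)
        assert ranked.feature_ids[0] == 0

    def test_constant_column_in_zero_tail(self):
        rng = np.random.default_rng(2)
        X, y = _labelled_matrix(rng, k=5)
        X[:, 3] = 1
        ranked = lasso_rank(X, y, alpha=0.001)
        assert ranked.scores[ranked.feature_ids.index(3)] == 0.0
        nonzero = sum(1 for s in ranked.scores if s > 0)
        assert ranked.feature_ids.index(3) >= nonzero

    def test_duplicated_informative_column_beats_noise(self):
        rng = np.random.default_rng(3)
        n = 300
        y = rng.integers(0, 2, size=n)
        noise = rng.integers(0, 3, size=(n, 4))
        X = np.column_stack([y, y, noise])
        ranked = lasso_rank(X, y, alpha=0.001)
        pos = {f: i for i, f in enumerate(ranked.feature_ids)}
        assert max(pos[0], pos[1]) < min(pos[f] for f in range(2, 6))

    def test_ranks_contiguous_and_restricted_to_input(self):
        rng = np.random.default_rng(4)
        X, y = _labelled_matrix(rng, k=6)
        ranked = lasso_rank(X, y, alpha=0.01, feature_ids=[10, 11, 12, 13, 14, 15])
        assert sorted(ranked.feature_ids) == [10, 11, 12, 13, 14, 15]


class TestGbdtRank:
    def test_label_column_ranks_first(self):
        rng = np.random.default_rng(5)
        X, y = _labelled_matrix(rng, n=300)
        ranked = gbdt_rank(X, y, n_trees=50, seed=0)
        assert ranked.feature_ids[0] == 0

    def test_constant_column_in_tail(self):
        rng = np.random.default_rng(6)
        X, y = _labelled_matrix(rng, n=300, k=5)
        X[:, 4] = 0
        ranked = gbdt_rank(X, y, n_trees=50, seed=0)
        assert ranked.scores[ranked.feature_ids.index(4)] == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X, y = _labelled_matrix(rng, n=250)
        a = gbdt_rank(X, y, n_trees=40, seed=11)
        b = gbdt_rank(X, y, n_trees=40, seed=11)
        assert a.feature_ids == b.feature_ids and a.scores == b.scores

    def test_degenerate_fit_warns_and_ties_by_id(self):
        X = np.zeros((30, 4), dtype=int)
        y = np.array([0, 1] * 15)
        with pytest.warns(UserWarning, match="no splits"):
            ranked = gbdt_rank(X, y, n_trees=5, seed=0)
        assert ranked.feature_ids == [0, 1, 2, 3]


class TestMutualInformation:
    def test_matches_dictionary_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.integers(0, 3, size=40)
            y = rng.integers(0, 2, size=40)
            assert mutual_information(x, y) == pytest.approx(mi_oracle(x, y))

    def test_independent_blocks_have_zero_mi(self):
        x = np.array([0, 0, 1, 1])
        y = np.array([0, 1, 0, 1])
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_self_information_is_entropy(self):
        x = np.array([0, 0, 1, 2])
        h = -(0.5 * np.log(0.5) + 0.25 * np.log(0.25) * 2)
        assert mutual_information(x, x) == pytest.approx(h)


class TestMrmrRank:
    def test_first_pick_maximizes_relevance(self):
        rng = np.random.default_rng(9)
        X, y = _labelled_matrix(rng, n=60, k=6)
        ranked = mrmr_rank(X, y)
        rels = [mi_oracle(X[:, j], y) for j in range(6)]
        assert ranked.feature_ids[0] == int(np.argmax(rels))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        for trial in range(15):
            n = int(rng.integers(12, 31))
            k = int(rng.integers(2, 7))
            X = rng.integers(0, 3, size=(n, k))
            y = rng.integers(0, 2, size=n)
            ranked = mrmr_rank(X, y)
            assert ranked.feature_ids == mrmr_oracle(X, y)

    def test_duplicate_of_selected_deferred(self):
        rng = np.random.default_rng(11)
        n = 400
        y = rng.integers(0, 2, size=n)
        # strong noisy copy of the label; its exact duplicate; an independent
        # weaker noisy copy with positive relevance and low redundancy
        strong = np.where(rng.random(n) < 0.9, y, 1 - y)
        weak = np.where(rng.random(n) < 0.75, y, 1 - y)
        X = np.column_stack([strong, strong, weak])
        ranked = mrmr_rank(X, y)
        assert ranked.feature_ids[0] == 0
        assert ranked.feature_ids[1] == 2  # the duplicate is maximally redundant

    def test_top_k_clamp_warns(self):
        rng = np.random.default_rng(12)
        X, y = _labelled_matrix(rng, n=30, k=3)
        with pytest.warns(UserWarning, match="clamping"):
            ranked = mrmr_rank(X, y, top_k=10)
        assert len(ranked) == 3


@pytest.mark.parametrize("algorithm", ["lasso", "mrmr"])
def test_permutation_equivariance(algorithm):
    """Permuting columns permutes ranks identically."""
    rng = np.random.default_rng(13)
    X, y = _labelled_matrix(rng, n=150, k=6)
    perm = np.array([3, 0, 5, 1, 4, 2])
    fids = list(range(6))

    def rank(Xin, ids):
        if algorithm == "lasso":
            return lasso_rank(Xin, y, alpha=0.005, feature_ids=ids)
        return mrmr_rank(Xin, y, feature_ids=ids)

    base = rank(X, fids)
    permuted = rank(X[:, perm], [fids[i] for i in perm])
    assert base.feature_ids == permuted.feature_ids


def test_gbdt_equivariance_for_separated_features():
    """Boosted-tree split selection breaks ties by column order, so exact
    equivariance only holds for features whose importance is decisively
    separated: two planted signals of different strength keep their positions
    under column permutation."""
    rng = np.random.default_rng(14)
    X, y = _labelled_matrix(rng, n=300, k=6)
    perm = np.array([4, 1, 5, 0, 3, 2])
    base = gbdt_rank(X, y, n_trees=50, seed=2, feature_ids=list(range(6)))
    permuted = gbdt_rank(
        X[:, perm], y, n_trees=50, seed=2, feature_ids=[int(i) for i in perm]
    )
    assert base.feature_ids[0] == permuted.feature_ids[0] == 0
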