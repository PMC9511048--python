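"""Feature-ranking algorithms applied to each balanced dataset.

Three schemes rank the filter-selected features:

* ``lasso`` — L1-penalized linear regression of the 0/1 label on standardized
  features; importance is the absolute coefficient.
* ``gbdt`` — gradient-boosted decision trees (LightGBM); importance is the
  number of splits using the feature.
* ``mrmr`` — greedy max-relevance min-redundancy with the difference
  criterion: the first pick maximizes I(f; y); each later pick maximizes
  I(f; y) − mean_{s in S} I(f; s) over the already-selected set S.

Mutual information is the empirical plug-in estimate on the discrete feature
alphabet (pair features take values in {0,1,2}), in natural-log units.  Ties
are always broken by ascending feature id so every list is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.preprocessing import StandardScaler

from .types import RankedList

logger = logging.getLogger(__name__)


def _as_dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def _order_desc_then_id(
    scores: np.ndarray, feature_ids: Sequence[int]
) -> list[int]:
    """Column order by descending score, ties by ascending feature id."""
    fids = np.asarray(feature_ids)
    idx = np.lexsort((fids, -np.asarray(scores, dtype=float)))
    return [int(i) for i in idx]


def _resolve_ids(X, feature_ids: Sequence[int] | None) -> list[int]:
    k = X.shape[1]
    if feature_ids is None:
        return list(range(k))
    feature_ids = [int(f) for f in feature_ids]
    if len(feature_ids) != k:
        raise ValueError("feature_ids length must match column count")
    return feature_ids


def lasso_rank(
    X,
    y,
    alpha: float = 0.01,
    *,
    feature_ids: Sequence[int] | None = None,
    dataset_id: int = 0,
    max_iter: int = 10_000,
) -> RankedList:
    """Rank by |coefficient| of an L1-penalized linear fit on standardized X.

    Zero-coefficient features come after all nonzero ones, in ascending
    feature-id order (their coefficients carry no ordering information).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    fids = _resolve_ids(X, feature_ids)
    Xd = _as_dense(X).astype(np.float64)
    Xs = StandardScaler().fit_transform(Xd)
    yv = np.asarray(y, dtype=np.float64)

    coef = None
    for attempt_iter in (max_iter, 10 * max_iter):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model = Lasso(alpha=alpha, max_iter=attempt_iter)
            model.fit(Xs, yv)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            coef = model.coef_
            break
        coef = model.coef_
    if coef is None:  # pragma: no cover - defensive
        raise RuntimeError("lasso failed to converge")

    abs_coef = np.abs(coef)
    nz = np.flatnonzero(abs_coef > 0)
    zero = np.flatnonzero(abs_coef == 0)
    order = _order_desc_then_id(abs_coef[nz], [fids[i] for i in nz])
    ordered_cols = [int(nz[i]) for i in order]
    ordered_cols += sorted((int(i) for i in zero), key=lambda i: fids[i])
    return RankedList(
        dataset_id=dataset_id,
        algorithm="lasso",
        feature_ids=[fids[i] for i in ordered_cols],
        scores=[float(abs_coef[i]) for i in ordered_cols],
    )


def gbdt_rank(
    X,
    y,
    n_trees: int = 100,
    seed: int = 0,
    *,
    feature_ids: Sequence[int] | None = None,
    dataset_id: int = 0,
) -> RankedList:
    """Rank by split count in a LightGBM gradient-boosted classifier."""
    import lightgbm as lgb

    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    fids = _resolve_ids(X, feature_ids)
    Xd = _as_dense(X).astype(np.float32)
    model = lgb.LGBMClassifier(
        n_estimators=n_trees,
        random_state=int(seed),
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbose=-1,
    )
    model.fit(Xd, np.asarray(y))
    counts = model.booster_.feature_importance(importance_type="split").astype(float)
    if counts.sum() == 0:
        warnings.warn("gradient boosting produced no splits; all features tie")
    order = _order_desc_then_id(counts, fids)
    return RankedList(
        dataset_id=dataset_id,
        algorithm="gbdt",
        feature_ids=[fids[i] for i in order],
        scores=[float(counts[i]) for i in order],
    )


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information of two discrete vectors, in nats."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / (px @ py)[mask])))


def _mi_columns_vs(ind: list[np.ndarray], v: np.ndarray, levels: int = 3) -> np.ndarray:
    """MI of every column against one discrete vector v, vectorized.

    ``ind[a]`` is the boolean indicator matrix (rows x cols) of value ``a``.
    """
    n = ind[0].shape[0]
    v = np.asarray(v).ravel()
    vals = np.unique(v)
    k = ind[0].shape[1]
    mi = np.zeros(k)
    # marginals of the columns
    px = np.stack([m.sum(axis=0) for m in ind]) / n  # levels x k
    with np.errstate(divide="ignore", invalid="ignore"):
        for b in vals:
            vb = (v == b).astype(np.float64)
            pb = vb.mean()
            for a in range(levels):
                pab = (ind[a].T @ vb) / n  # k
                term = pab * (np.log(pab) - np.log(px[a] * pb))
                mi += np.where(pab > 0, np.nan_to_num(term), 0.0)
    return mi


def _indicators(Xd: np.ndarray, levels: int = 3) -> list[np.ndarray]:
    return [(Xd == a).astype(np.float64) for a in range(levels)]


def mrmr_rank(
    X,
    y,
    top_k: int | None = None,
    *,
    feature_ids: Sequence[int] | None = None,
    dataset_id: int = 0,
) -> RankedList:
    """Greedy max-relevance min-redundancy ranking (difference criterion).

    Stops after ``top_k`` greedy picks; remaining features are appended in
    ascending feature-id order.  Features must be discrete with small
    alphabets (pair-feature values lie in {0,1,2}).
    """
    fids = _resolve_ids(X, feature_ids)
    Xd = _as_dense(X).astype(np.int64)
    if Xd.min() < 0 or Xd.max() > 2:
        raise ValueError("mrmr expects features with values in {0,1,2}")
    yv = np.asarray(y).ravel()
    k = Xd.shape[1]
    if top_k is None:
        top_k = k
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if top_k > k:
        warnings.warn(f"top_k={top_k} exceeds feature count {k}; clamping")
        top_k = k

    ind = _indicators(Xd)
    relevance = _mi_columns_vs(ind, yv)

    fid_arr = np.asarray(fids, dtype=np.int64)
    selected: list[int] = []  # column indices in greedy order
    remaining = np.ones(k, dtype=bool)
    redundancy_sum = np.zeros(k)

    scores: list[float] = []
    for step in range(top_k):
        if step == 0:
            crit = relevance.copy()
        else:
            crit = relevance - redundancy_sum / len(selected)
        crit_masked = np.where(remaining, crit, -np.inf)
        best = crit_masked.max()
        # values within 1e-9 are numeric ties, broken by ascending feature id
        cand = np.flatnonzero(crit_masked >= best - 1e-9)
        pick = int(cand[np.argmin(fid_arr[cand])])
        selected.append(pick)
        scores.append(float(crit[pick]))
        remaining[pick] = False
        if step < top_k - 1:
            redundancy_sum += _mi_columns_vs(ind, Xd[:, pick])

    tail = sorted((int(i) for i in np.flatnonzero(remaining)), key=lambda i: fids[i])
    ordered = selected + tail
    return RankedList(
        dataset_id=dataset_id,
        algorithm="mrmr",
        feature_ids=[fids[i] for i in ordered],
        scores=scores + [0.0] * len(tail),
    )
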