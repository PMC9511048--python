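"""Shadow-feature (Boruta-style) all-relevant filtering.

Each iteration appends a column-shuffled ("shadow") copy of every surviving
feature to the matrix, fits a random forest, and records a hit for every real
feature whose impurity importance strictly exceeds the best shadow
importance.  Hit counts are tested against Binomial(iterations, 1/2) with a
Bonferroni correction: features significantly above expectation are accepted,
significantly below are rejected and leave the matrix.  Features still
undecided when iterations run out are handled by the tentative policy
(rejected by default; optionally accepted when their median importance beats
the median of the per-iteration shadow maxima).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from typing import Sequence

import numpy as np
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier

from ._rng import stream, stream_seed
from .types import FilterResult, PairFeatureMatrix

logger = logging.getLogger(__name__)

UNDECIDED, ACCEPTED, REJECTED = 0, 1, -1


def boruta_filter(
    matrix: PairFeatureMatrix,
    max_iter: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    n_estimators: int = 100,
    tentative_policy: str = "reject",
) -> FilterResult:
    """Run the shadow-feature loop on one balanced dataset.

    Parameters
    ----------
    matrix
        Encoded pair-feature matrix with 0/1 labels.
    max_iter
        Maximum number of shuffle/fit/compare iterations; the loop stops
        early once every feature is accepted or rejected.
    seed
        Master seed; each iteration's shuffle and forest draw from their own
        derived streams.
    alpha
        Two-sided significance level for the binomial hit test, Bonferroni
        corrected over the number of real features.
    n_estimators
        Trees per random forest.
    tentative_policy
        ``"reject"`` (conservative default) or ``"median"`` (accept an
        undecided feature whose median importance exceeds the median of the
        per-iteration shadow maxima).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tentative_policy not in ("reject", "median"):
        raise ValueError(f"unknown tentative policy {tentative_policy!r}")
    y = np.asarray(matrix.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; cannot filter")

    X_full = np.asarray(matrix.X.todense(), dtype=np.float32)
    n_feat = X_full.shape[1]
    col_ptp = X_full.max(axis=0) - X_full.min(axis=0)
    if np.all(col_ptp == 0):
        warnings.warn("all features are constant; nothing can be selected")
        return FilterResult(matrix.dataset_id, frozenset(), 0, [])

    decision = np.zeros(n_feat, dtype=np.int8)
    hits = np.zeros(n_feat, dtype=np.int64)
    imp_history: list[np.ndarray] = []  # per-iteration importances, NaN when inactive
    shadow_max_history: list[float] = []
    history: list[dict] = []
    bonferroni = n_feat

    it = 0
    for it in range(1, max_iter + 1):
        active = np.flatnonzero(decision >= 0)  # undecided + accepted stay in the model
        undecided = np.flatnonzero(decision == 0)
        if undecided.size == 0:
            it -= 1
            break
        Xa = X_full[:, active]

        rng = stream(seed, "shadow", it)
        # at least 5 shadow columns so the max-shadow null is not degenerate
        shadow_src = Xa
        while shadow_src.shape[1] < 5:
            shadow_src = np.hstack([shadow_src, Xa])
        shadows = shadow_src.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])

        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            n_jobs=1,
            random_state=stream_seed(seed, "forest", it),
        )
        rf.fit(np.hstack([Xa, shadows]), y)
        imp = rf.feature_importances_
        real_imp = imp[: Xa.shape[1]]
        shadow_max = float(imp[Xa.shape[1] :].max())
        shadow_max_history.append(shadow_max)

        row = np.full(n_feat, np.nan)
        row[active] = real_imp
        imp_history.append(row)

        hit_mask = np.zeros(n_feat, dtype=bool)
        hit_mask[active] = real_imp > shadow_max
        hits[undecided] += hit_mask[undecided]

        # two-sided binomial test at this iteration count, Bonferroni corrected
        p_acc = binom.sf(hits[undecided] - 1, it, 0.5)
        p_rej = binom.cdf(hits[undecided], it, 0.5)
        decision[undecided[p_acc * bonferroni < alpha]] = ACCEPTED
        decision[undecided[p_rej * bonferroni < alpha]] = REJECTED

        history.append(
            {
                "iteration": it,
                "n_active": int(active.size),
                "shadow_max": shadow_max,
                "n_hits": int(hit_mask.sum()),
                "n_accepted": int((decision == ACCEPTED).sum()),
                "n_rejected": int((decision == REJECTED).sum()),
            }
        )

    if tentative_policy == "median" and (decision == UNDECIDED).any():
        imp_mat = np.vstack(imp_history)
        shadow_median = float(np.median(shadow_max_history))
        for f in np.flatnonzero(decision == UNDECIDED):
            med = np.nanmedian(imp_mat[:, f])
            if np.isfinite(med) and med > shadow_median:
                decision[f] = ACCEPTED

    selected = frozenset(int(f) for f in np.flatnonzero(decision == ACCEPTED))
    return FilterResult(matrix.dataset_id, selected, it, history)


def union_selected(
    results: Sequence[FilterResult],
) -> tuple[frozenset[int], Counter]:
    """Union of per-dataset selections plus per-feature selection counts."""
    if not results:
        raise ValueError("need at least one filter result")
    counts: Counter = Counter()
    for r in results:
        counts.update(r.selected)
    return frozenset(counts), counts
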