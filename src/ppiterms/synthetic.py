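"""Synthetic protein universes with planted signal terms.

The generator emulates the statistical structure the pipeline assumes: a
protein universe with sparse binary GO/KEGG annotations, and a positive
interaction set whose pairs preferentially share a small set of "signal"
terms.  Negatives are whatever pairs are not positive, so the class imbalance
is controlled by the universe size.  Because the signal terms are known,
end-to-end recovery of planted ground truth is measurable.

Defaults are the desk-scale study conditions used throughout the test suite:
500 proteins, 200 GO terms + 30 KEGG pathways, 10 signal terms, 2,000
positive pairs, 20x odds enrichment for signal-sharing pairs, background
annotation prevalence 0.03 and signal-term prevalence 0.15 (sparse profiles
with a realistic chance that a random pair shares a signal term).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rng import stream
from .types import (
    AnnotationCatalog,
    FeatureDescriptor,
    InteractionTable,
    Pair,
    ProteinProfile,
    canonical_pair,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic universe."""

    n_proteins: int = 500
    n_go: int = 200
    n_kegg: int = 30
    base_prevalence: float = 0.03
    n_signal: int = 10
    signal_prevalence: float = 0.15
    n_pos: int = 2000
    enrichment: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("n_proteins must be >= 2")
        if self.n_go < 0 or self.n_kegg < 0 or self.n_go + self.n_kegg < 1:
            raise ValueError("need at least one annotation term")
        if not (0 < self.base_prevalence < 1):
            raise ValueError("base_prevalence must be in (0,1)")
        if not (0 < self.signal_prevalence < 1):
            raise ValueError("signal_prevalence must be in (0,1)")
        if self.n_signal < 0 or self.n_signal > self.n_go + self.n_kegg:
            raise ValueError("n_signal must be in [0, n_go + n_kegg]")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        max_pairs = self.n_proteins * (self.n_proteins - 1) // 2
        if not (1 <= self.n_pos <= max_pairs):
            raise ValueError(f"n_pos must be in [1, C(n_proteins,2)={max_pairs}]")


@dataclass(frozen=True)
class SyntheticTruth:
    """The planted ground truth: signal terms and their derived feature names."""

    signal_terms: frozenset[str]
    signal_features: frozenset[str]  # machine names, sum:<term> and absdiff:<term>

    @staticmethod
    def from_terms(terms: Sequence[str]) -> "SyntheticTruth":
        feats = {f"sum:{t}" for t in terms} | {f"absdiff:{t}" for t in terms}
        return SyntheticTruth(frozenset(terms), frozenset(feats))


def _choose_signal_terms(cfg: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    """Signal terms drawn from both channels (proportional, each channel gets
    at least one when it can)."""
    go_ids = [f"GO:{i + 1:07d}" for i in range(cfg.n_go)]
    kegg_ids = [f"hsa{i + 1:05d}" for i in range(cfg.n_kegg)]
    if cfg.n_signal == 0:
        return []
    total = cfg.n_go + cfg.n_kegg
    n_kegg_sig = int(round(cfg.n_signal * cfg.n_kegg / total)) if cfg.n_kegg else 0
    if cfg.n_kegg and cfg.n_go and cfg.n_signal >= 2:
        n_kegg_sig = min(max(n_kegg_sig, 1), cfg.n_kegg, cfg.n_signal - 1)
    n_go_sig = min(cfg.n_signal - n_kegg_sig, cfg.n_go)
    n_kegg_sig = cfg.n_signal - n_go_sig
    chosen = list(rng.choice(go_ids, size=n_go_sig, replace=False)) + list(
        rng.choice(kegg_ids, size=n_kegg_sig, replace=False)
    )
    return [str(t) for t in chosen]


def generate(
    cfg: SyntheticConfig,
) -> tuple[AnnotationCatalog, list[ProteinProfile], InteractionTable, SyntheticTruth]:
    """Generate catalog, profiles, positive interactions, and the truth.

    Annotations are independent Bernoulli draws per (protein, term) at the
    background prevalence, or the signal prevalence for signal terms; a
    protein drawing no term at all is redrawn.  Positive pairs are taken by
    rejection sampling: a candidate pair sharing at least one signal term is
    accepted with odds ``enrichment`` times those of a non-sharing pair, so
    ``enrichment = 1`` plants no signal at all.  Deterministic given the seed.
    """
    cfg.validate()
    go_ids = [f"GO:{i + 1:07d}" for i in range(cfg.n_go)]
    kegg_ids = [f"hsa{i + 1:05d}" for i in range(cfg.n_kegg)]
    catalog = AnnotationCatalog(tuple(go_ids), tuple(kegg_ids))

    sig_rng = stream(cfg.seed, "signal_terms")
    signal_terms = _choose_signal_terms(cfg, sig_rng)
    truth = SyntheticTruth.from_terms(signal_terms)
    sig_set = set(signal_terms)

    # per-term prevalence vectors
    p_go = np.full(cfg.n_go, cfg.base_prevalence)
    p_kegg = np.full(cfg.n_kegg, cfg.base_prevalence)
    for i, t in enumerate(go_ids):
        if t in sig_set:
            p_go[i] = cfg.signal_prevalence
    for i, t in enumerate(kegg_ids):
        if t in sig_set:
            p_kegg[i] = cfg.signal_prevalence

    ann_rng = stream(cfg.seed, "annotations")
    go_mat = ann_rng.random((cfg.n_proteins, cfg.n_go)) < p_go
    kegg_mat = ann_rng.random((cfg.n_proteins, cfg.n_kegg)) < p_kegg
    empty = ~(go_mat.any(axis=1) | kegg_mat.any(axis=1))
    attempts = 0
    while empty.any():
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("could not annotate every protein; prevalence too low")
        idx = np.flatnonzero(empty)
        go_mat[idx] = ann_rng.random((idx.size, cfg.n_go)) < p_go
        kegg_mat[idx] = ann_rng.random((idx.size, cfg.n_kegg)) < p_kegg
        empty = ~(go_mat.any(axis=1) | kegg_mat.any(axis=1))

    width = len(str(cfg.n_proteins))
    pids = [f"P{i + 1:0{width}d}" for i in range(cfg.n_proteins)]
    profiles = [
        ProteinProfile(
            pids[i],
            frozenset(int(j) for j in np.flatnonzero(go_mat[i])),
            frozenset(int(j) for j in np.flatnonzero(kegg_mat[i])),
        )
        for i in range(cfg.n_proteins)
    ]

    # signal-annotation matrix over proteins for fast sharing checks
    sig_cols_go = [i for i, t in enumerate(go_ids) if t in sig_set]
    sig_cols_kegg = [i for i, t in enumerate(kegg_ids) if t in sig_set]
    sig_mat = np.hstack(
        [go_mat[:, sig_cols_go], kegg_mat[:, sig_cols_kegg]]
    ) if sig_cols_go or sig_cols_kegg else np.zeros((cfg.n_proteins, 0), dtype=bool)

    pos_rng = stream(cfg.seed, "positives")
    accept_nonsharing = 1.0 / cfg.enrichment
    chosen: set[Pair] = set()
    pairs: list[Pair] = []
    max_draws = 500 * max(cfg.n_pos, 1000)
    draws = 0
    while len(pairs) < cfg.n_pos:
        k = max(256, 2 * (cfg.n_pos - len(pairs)))
        ii = pos_rng.integers(0, cfg.n_proteins, size=k)
        jj = pos_rng.integers(0, cfg.n_proteins, size=k)
        us = pos_rng.random(size=k)
        draws += k
        if draws > max_draws:
            raise RuntimeError(
                f"could not place {cfg.n_pos} positive pairs; configuration infeasible"
            )
        for i, j, u in zip(ii, jj, us):
            if i == j:
                continue
            shares = bool((sig_mat[i] & sig_mat[j]).any()) if sig_mat.shape[1] else False
            if not shares and u >= accept_nonsharing:
                continue
            p = canonical_pair(pids[i], pids[j])
            if p in chosen:
                continue
            chosen.add(p)
            pairs.append(p)
            if len(pairs) == cfg.n_pos:
                break

    pairs.sort()
    table = InteractionTable(pairs=pairs, scores=np.ones(len(pairs)))
    return catalog, profiles, table, truth


def recovery_rate(
    truth: SyntheticTruth,
    integrated_features: Sequence[str | FeatureDescriptor],
    top_n: int,
) -> float:
    """Fraction of signal terms with at least one derived feature in the top n.

    ``integrated_features`` is the consensus ordering, as machine names
    (``sum:<term>``/``absdiff:<term>``) or feature descriptors.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not integrated_features:
        raise ValueError("integrated feature list is empty")
    if not truth.signal_terms:
        raise ValueError("truth contains no signal terms")
    names = [
        f.name if isinstance(f, FeatureDescriptor) else str(f)
        for f in integrated_features[:top_n]
    ]
    hit_terms = {
        name.split(":", 1)[1] for name in names if name in truth.signal_features
    }
    return len(hit_terms) / len(truth.signal_terms)


def rank_separation(
    truth: SyntheticTruth,
    ranked_names: Sequence[str],
    universe_names: Sequence[str],
    n_perm: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean-rank separation of signal-derived vs background features.

    Every feature of the universe gets a rank: its 1-based position in the
    integrated list, or ``len(ranked_names) + 1`` when absent (unranked
    features are worse than any ranked one).  Returns ``(stat, p)`` where
    ``stat = mean rank of signal features - mean rank of background
    features`` (negative = signal ranks better) and ``p`` is a two-sided
    permutation p-value for the null of no separation.
    """
    ranked_names = [str(n) for n in ranked_names]
    universe_names = [str(n) for n in universe_names]
    if not universe_names:
        raise ValueError("empty feature universe")
    pos = {n: i + 1 for i, n in enumerate(ranked_names)}
    worst = len(ranked_names) + 1
    ranks = np.array([pos.get(n, worst) for n in universe_names], dtype=float)
    is_signal = np.array([n in truth.signal_features for n in universe_names])
    n_sig = int(is_signal.sum())
    if n_sig == 0 or n_sig == len(universe_names):
        raise ValueError("need both signal and background features in the universe")

    stat = float(ranks[is_signal].mean() - ranks[~is_signal].mean())
    rng = stream(seed, "rank_separation")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(is_signal)
        s = ranks[perm].mean() - ranks[~perm].mean()
        if abs(s) >= abs(stat) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return stat, p


def write_synthetic_inputs(
    catalog: AnnotationCatalog,
    profiles: Sequence[ProteinProfile],
    table: InteractionTable,
    truth: SyntheticTruth,
    cfg: SyntheticConfig,
    out_dir,
) -> dict[str, Path]:
    """Persist the generated universe in the exact formats the readers accept."""
    from . import io as io_mod

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": io_mod.write_interactions(table, out_dir / "interactions.tsv"),
        "go": io_mod.write_annotation_tsv(profiles, catalog, "GO", out_dir / "go.tsv"),
        "kegg": io_mod.write_annotation_tsv(
            profiles, catalog, "KEGG", out_dir / "kegg.tsv"
        ),
    }
    truth_path = out_dir / "truth.json"
    with truth_path.open("w") as fh:
        json.dump(
            {
                "signal_terms": sorted(truth.signal_terms),
                "signal_features": sorted(truth.signal_features),
                "config": asdict(cfg),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    paths["truth"] = truth_path
    return paths
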