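"""End-to-end orchestration: ingest/synth -> datasets -> encode -> filter ->
rank -> integrate -> venn -> report.

A single master seed deterministically derives every stage's random stream
(``hash(master_seed, stage, dataset_id)``), so identical configuration yields
byte-identical output files.  Per-dataset stage results are cached on disk
under ``<out_dir>/cache`` keyed by a digest of the stage's inputs, and reused
on rerun when nothing upstream changed.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from . import io as io_mod
from ._rng import stream_seed
from .boruta import boruta_filter, union_selected
from .consensus import integrate, render_report, top_n, venn
from .datasets import build_datasets, num_subsets, partition, sample_negatives
from .encoding import build_descriptors, encode_dataset
from .rankers import gbdt_rank, lasso_rank, mrmr_rank
from .synthetic import SyntheticConfig, generate
from .types import profiles_by_id

logger = logging.getLogger(__name__)

KNOWN_ALGORITHMS = ("lasso", "gbdt", "mrmr")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``synthetic`` is set (generate the universe in memory) or the three
    input paths are set.  ``k`` is the number of balanced datasets: "auto"
    derives floor(negatives/positives) from the full negative complement;
    an integer K samples K * |positives| negatives instead.
    """

    interactions_path: str | None = None
    go_path: str | None = None
    kegg_path: str | None = None
    synthetic: SyntheticConfig | None = None
    score_threshold: float = 0.0
    k: int | str = "auto"
    algorithms: tuple[str, ...] = ("lasso", "gbdt", "mrmr")
    boruta_max_iter: int = 100
    boruta_alpha: float = 0.05
    boruta_trees: int = 100
    boruta_tentative_policy: str = "reject"
    skip_filter: bool = False
    lasso_alpha: float = 0.01
    gbdt_trees: int = 100
    mrmr_top_k: int = 500
    top_n: int = 100
    seed: int = 0
    out_dir: str = "ppiterms_out"
    use_cache: bool = True

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "algorithms" in raw:
            raw["algorithms"] = tuple(raw["algorithms"])
        return RunConfig(**raw)


def validate(cfg: RunConfig) -> list[str]:
    """Return a list of configuration problems; empty means valid."""
    problems: list[str] = []
    if cfg.synthetic is None:
        for name in ("interactions_path", "go_path", "kegg_path"):
            p = getattr(cfg, name)
            if p is None:
                problems.append(f"{name} missing and no synthetic config given")
            elif not Path(p).exists():
                problems.append(f"{name}: file not found: {p}")
    else:
        try:
            cfg.synthetic.validate()
        except ValueError as exc:
            problems.append(f"synthetic: {exc}")
    if cfg.score_threshold < 0:
        problems.append("score_threshold must be >= 0")
    if cfg.k != "auto" and (not isinstance(cfg.k, int) or cfg.k < 1):
        problems.append("k must be 'auto' or a positive integer")
    for alg in cfg.algorithms:
        if alg not in KNOWN_ALGORITHMS:
            problems.append(f"unknown algorithm {alg!r}")
    if not cfg.algorithms:
        problems.append("no ranking algorithms configured")
    if cfg.top_n < 1:
        problems.append("top_n must be >= 1")
    if cfg.boruta_max_iter < 1:
        problems.append("boruta_max_iter must be >= 1")
    if not (0 < cfg.boruta_alpha < 1):
        problems.append("boruta_alpha must be in (0,1)")
    if cfg.lasso_alpha <= 0:
        problems.append("lasso_alpha must be > 0")
    if cfg.gbdt_trees < 1 or cfg.boruta_trees < 1:
        problems.append("tree counts must be >= 1")
    if cfg.mrmr_top_k < 1:
        problems.append("mrmr_top_k must be >= 1")
    return problems


@dataclass
class RunResult:
    manifest: list[Path]
    consensus: dict
    venn: object
    report: dict
    metadata: dict
    truth: object | None = None
    catalog: object | None = None
    descriptors: list | None = None


def _digest(*parts: object) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(repr(p).encode())
        h.update(b"\x00")
    return h.hexdigest()[:16]


class _Cache:
    def __init__(self, root: Path, enabled: bool):
        self.root = root
        self.enabled = enabled
        if enabled:
            root.mkdir(parents=True, exist_ok=True)
        self.hits: list[str] = []

    def get_or_compute(self, stage: str, key: str, fn):
        if not self.enabled:
            return fn()
        path = self.root / f"{stage}-{key}.pkl"
        if path.exists():
            with path.open("rb") as fh:
                self.hits.append(f"{stage}-{key}")
                return pickle.load(fh)
        value = fn()
        with path.open("wb") as fh:
            pickle.dump(value, fh)
        return value


def run(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline and write all outputs."""
    problems = validate(cfg)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))

    t0 = time.time()
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    out_dir = Path(cfg.out_dir)
    cache = _Cache(out_dir / "cache", cfg.use_cache)

    # --- stage: inputs -----------------------------------------------------
    t = time.time()
    truth = None
    if cfg.synthetic is not None:
        catalog, profiles, positives, truth = generate(cfg.synthetic)
    else:
        positives = io_mod.read_interactions(cfg.interactions_path, cfg.score_threshold)
        catalog, profiles = io_mod.read_annotations(cfg.go_path, cfg.kegg_path)
        positives = io_mod.restrict_to_annotated(positives, profiles)
    prof_map = profiles_by_id(profiles)
    universe = sorted(positives.proteins & set(prof_map))
    counts["proteins"] = len(universe)
    counts["positives"] = len(positives)
    timings["inputs"] = time.time() - t

    # --- stage: negatives + balanced datasets ------------------------------
    t = time.time()
    neg_seed = stream_seed(cfg.seed, "negatives")
    if cfg.k == "auto":
        negatives = sample_negatives(universe, positives, "all", neg_seed)
        k = num_subsets(len(negatives), len(positives))
    else:
        k = int(cfg.k)
        negatives = sample_negatives(
            universe, positives, k * len(positives), neg_seed
        )
    subsets = partition(negatives, k, stream_seed(cfg.seed, "partition"))
    datasets = build_datasets(positives, subsets)
    counts["negatives"] = len(negatives)
    counts["datasets"] = k
    timings["datasets"] = time.time() - t

    descriptors = build_descriptors(catalog)
    input_digest = _digest(
        cfg.synthetic, cfg.interactions_path, cfg.go_path, cfg.kegg_path,
        cfg.score_threshold, cfg.k, cfg.seed, counts["proteins"], counts["positives"],
    )

    # --- per-dataset stages: encode -> filter -> rank -----------------------
    filter_results = []
    ranked: dict[str, list] = {alg: [] for alg in cfg.algorithms}
    t = time.time()
    for ds in datasets:
        matrix = encode_dataset(ds, prof_map, catalog)

        if cfg.skip_filter:
            selected = list(range(matrix.n_features))
        else:
            fkey = _digest(
                input_digest, ds.dataset_id, cfg.boruta_max_iter, cfg.boruta_alpha,
                cfg.boruta_trees, cfg.boruta_tentative_policy,
            )
            fres = cache.get_or_compute(
                "filter",
                fkey,
                lambda: boruta_filter(
                    matrix,
                    max_iter=cfg.boruta_max_iter,
                    seed=stream_seed(cfg.seed, "filter", ds.dataset_id),
                    alpha=cfg.boruta_alpha,
                    n_estimators=cfg.boruta_trees,
                    tentative_policy=cfg.boruta_tentative_policy,
                ),
            )
            filter_results.append(fres)
            selected = sorted(fres.selected)
        if not selected:
            logger.warning("dataset %d: no features selected; skipping ranking",
                           ds.dataset_id)
            continue

        Xsel = matrix.X[:, selected]
        y = matrix.labels
        for alg in cfg.algorithms:
            rkey = _digest(
                input_digest, ds.dataset_id, alg, cfg.skip_filter, cfg.lasso_alpha,
                cfg.gbdt_trees, cfg.mrmr_top_k, cfg.boruta_max_iter,
                cfg.boruta_alpha, cfg.boruta_trees,
            )

            def _rank(alg=alg, Xsel=Xsel, y=y, selected=selected, ds=ds):
                if alg == "lasso":
                    return lasso_rank(
                        Xsel, y, alpha=cfg.lasso_alpha,
                        feature_ids=selected, dataset_id=ds.dataset_id,
                    )
                if alg == "gbdt":
                    return gbdt_rank(
                        Xsel, y, n_trees=cfg.gbdt_trees,
                        seed=stream_seed(cfg.seed, "gbdt", ds.dataset_id),
                        feature_ids=selected, dataset_id=ds.dataset_id,
                    )
                return mrmr_rank(
                    Xsel, y, top_k=min(cfg.mrmr_top_k, len(selected)),
                    feature_ids=selected, dataset_id=ds.dataset_id,
                )

            ranked[alg].append(cache.get_or_compute("rank", rkey, _rank))
    timings["filter_rank"] = time.time() - t

    if filter_results:
        union, sel_counts = union_selected(filter_results)
        counts["selected_union"] = len(union)
    else:
        counts["selected_union"] = len(descriptors) if cfg.skip_filter else 0

    # --- consensus + venn ---------------------------------------------------
    t = time.time()
    consensus = {}
    tops = {}
    for alg in cfg.algorithms:
        lists = ranked[alg]
        if not lists:
            logger.warning("algorithm %s produced no ranked lists", alg)
            consensus[alg] = []
            tops[alg] = set()
            continue
        consensus[alg] = integrate(lists, k)
        tops[alg] = set(top_n(consensus[alg], cfg.top_n))
    venn_partition = venn(tops) if len(tops) == 3 else None
    timings["consensus"] = time.time() - t

    boruta_counts = {fr.dataset_id: len(fr.selected) for fr in filter_results}
    report = render_report(
        consensus,
        venn_partition if venn_partition is not None else venn(
            {a: set() for a in ("lasso", "gbdt", "mrmr")}
        ),
        descriptors,
        top=cfg.top_n,
        boruta_counts=boruta_counts,
    )

    timings["total"] = time.time() - t0
    metadata = {
        "config": _config_dict(cfg),
        "counts": counts,
        "timings_s": {k_: round(v, 3) for k_, v in timings.items()},
        "cached_stages": cache.hits,
        "k": k,
    }
    manifest = io_mod.write_outputs(
        consensus, venn_partition, descriptors, out_dir, metadata
    )
    for name, frame in report.items():
        path = out_dir / f"report_{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        manifest.append(path)

    return RunResult(
        manifest=manifest,
        consensus=consensus,
        venn=venn_partition,
        report=report,
        metadata=metadata,
        truth=truth,
        catalog=catalog,
        descriptors=descriptors,
    )


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    if cfg.synthetic is not None:
        d["synthetic"] = asdict(cfg.synthetic)
    return d
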