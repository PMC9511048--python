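"""Reading interaction tables and annotation maps; writing pipeline outputs.

Input formats
-------------
* Interaction TSV: ``protein1<TAB>protein2<TAB>experimental_score`` with
  optional further columns; lines starting with ``#`` are comments.  Pairs are
  kept when the score strictly exceeds the threshold, canonicalized
  (lexicographic order), de-duplicated, and self-pairs are dropped.
* Annotation maps: either two-column TSV (``protein<TAB>term``) or a gene-set
  (GMT-style) layout (``term<TAB>description<TAB>member...``); the layout is
  auto-detected per file or forced via ``fmt``.

Outputs are plain TSV/JSON with fixed ordering and number formatting so a
rerun with the same seed and configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .types import (
    AnnotationCatalog,
    ConsensusRecord,
    FeatureDescriptor,
    InteractionTable,
    ProteinProfile,
    VennPartition,
    canonical_pair,
)

logger = logging.getLogger(__name__)


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def read_interactions(path, score_threshold: float = 0.0) -> InteractionTable:
    """Read a tab-separated interaction table, keeping pairs with score > threshold."""
    if score_threshold < 0:
        raise ValueError("score_threshold must be >= 0")
    path = Path(path)
    best: dict[tuple[str, str], float] = {}
    n_self = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(parts)}"
                )
            a, b = parts[0].strip(), parts[1].strip()
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed score {parts[2]!r}") from exc
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty protein identifier")
            if a == b:
                n_self += 1
                continue
            if score <= score_threshold:
                continue
            p = canonical_pair(a, b)
            if p not in best or score > best[p]:
                best[p] = score
    if n_self:
        logger.info("dropped %d self-pairs from %s", n_self, path)
    if not best:
        raise ValueError("no interactions passed threshold")
    pairs = sorted(best)
    return InteractionTable(pairs=pairs, scores=np.array([best[p] for p in pairs]))


def _detect_format(path: Path) -> str:
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ncol = len(line.split("\t"))
            if ncol >= 3:
                return "gmt"
    return "tsv"


def _read_annotation_file(path: Path, fmt: str) -> dict[str, set[str]]:
    """protein -> set of term ids."""
    if fmt == "auto":
        fmt = _detect_format(path)
    mapping: dict[str, set[str]] = defaultdict(set)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if fmt == "tsv":
                if len(parts) != 2 or not parts[0] or not parts[1]:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'protein<TAB>term'"
                    )
                mapping[parts[0]].add(parts[1])
            elif fmt == "gmt":
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: gene-set rows need term, description, members"
                    )
                term = parts[0]
                for member in parts[2:]:
                    if member:
                        mapping[member].add(term)
            else:
                raise ValueError(f"unknown annotation format {fmt!r}")
    return dict(mapping)


def read_annotations(
    go_path, kegg_path, fmt: str = "auto"
) -> tuple[AnnotationCatalog, list[ProteinProfile]]:
    """Read GO and KEGG annotation maps into a catalog and protein profiles.

    Catalog term order is the sorted order of identifiers within each channel,
    so feature indices are reproducible across runs and machines.
    """
    go_map = _read_annotation_file(Path(go_path), fmt)
    kegg_map = _read_annotation_file(Path(kegg_path), fmt)

    go_terms = sorted({t for ts in go_map.values() for t in ts})
    kegg_terms = sorted({t for ts in kegg_map.values() for t in ts})
    shared = set(go_terms) & set(kegg_terms)
    if shared:
        raise ValueError(
            f"terms present in both GO and KEGG files: {sorted(shared)[:5]}"
        )
    catalog = AnnotationCatalog(tuple(go_terms), tuple(kegg_terms))
    gidx, kidx = catalog.go_index(), catalog.kegg_index()

    profiles: list[ProteinProfile] = []
    n_dropped = 0
    for pid in sorted(set(go_map) | set(kegg_map)):
        gs = frozenset(gidx[t] for t in go_map.get(pid, ()))
        ks = frozenset(kidx[t] for t in kegg_map.get(pid, ()))
        if not gs and not ks:
            n_dropped += 1
            continue
        profiles.append(ProteinProfile(pid, gs, ks))
    if n_dropped:
        logger.info("dropped %d proteins with no annotations", n_dropped)
    return catalog, profiles


def restrict_to_annotated(
    table: InteractionTable, profiles: Sequence[ProteinProfile]
) -> InteractionTable:
    """Keep only pairs whose both endpoints have an annotation profile."""
    known = {p.protein_id for p in profiles}
    keep = [i for i, (a, b) in enumerate(table.pairs) if a in known and b in known]
    dropped = len(table) - len(keep)
    if dropped:
        logger.info("dropped %d pairs with unannotated endpoints", dropped)
    if not keep:
        raise ValueError("no interaction pair has both endpoints annotated")
    return InteractionTable(
        pairs=[table.pairs[i] for i in keep], scores=table.scores[keep]
    )


def write_interactions(table: InteractionTable, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#protein1\tprotein2\texperimental_score\n")
        for (a, b), s in zip(table.pairs, table.scores):
            fh.write(f"{a}\t{b}\t{_fmt(s)}\n")
    return path


def write_annotation_tsv(
    profiles: Sequence[ProteinProfile], catalog: AnnotationCatalog, channel: str, path
) -> Path:
    """Two-column protein<TAB>term map for one channel."""
    terms = catalog.go_terms if channel == "GO" else catalog.kegg_pathways
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#protein\tterm\n")
        for prof in sorted(profiles, key=lambda p: p.protein_id):
            idxs = prof.go_set if channel == "GO" else prof.kegg_set
            for i in sorted(idxs):
                fh.write(f"{prof.protein_id}\t{terms[i]}\n")
    return path


def write_outputs(
    consensus: Mapping[str, Sequence[ConsensusRecord]],
    venn_partition: VennPartition | None,
    descriptors: Sequence[FeatureDescriptor],
    out_dir,
    metadata: Mapping | None = None,
) -> list[Path]:
    """Write integrated lists, the Venn membership table, and run metadata.

    Returns the list of written paths (the manifest).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    desc_by_id = {d.feature_id: d for d in descriptors}
    manifest: list[Path] = []

    for alg in sorted(consensus):
        path = out_dir / f"integrated_{alg}.tsv"
        with path.open("w") as fh:
            fh.write(
                "rank\tfeature_id\tfeature\tdisplay_name\tN\tM\tW\timportance_score\n"
            )
            for rank, rec in enumerate(consensus[alg], start=1):
                d = desc_by_id[rec.feature_id]
                fh.write(
                    f"{rank}\t{rec.feature_id}\t{d.name}\t{d.display_name}\t{rec.n_f}"
                    f"\t{_fmt(rec.m_f)}\t{_fmt(rec.w_f)}\t{_fmt(rec.score)}\n"
                )
        manifest.append(path)

    venn_path = out_dir / "venn.tsv"
    with venn_path.open("w") as fh:
        fh.write("feature_id\tfeature\tdisplay_name\tn_algorithms\talgorithms\n")
        if venn_partition is not None:
            rows = []
            for f in venn_partition.triple:
                rows.append((f, 3, ",".join(sorted(consensus))))
            for f, labs in venn_partition.double.items():
                rows.append((f, 2, ",".join(sorted(labs))))
            for f, lab in venn_partition.single.items():
                rows.append((f, 1, lab))
            for f, n, labs in sorted(rows, key=lambda r: (-r[1], r[0])):
                d = desc_by_id[f]
                fh.write(f"{f}\t{d.name}\t{d.display_name}\t{n}\t{labs}\n")
    manifest.append(venn_path)

    meta_path = out_dir / "run_metadata.json"
    with meta_path.open("w") as fh:
        json.dump(dict(metadata or {}), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    manifest.append(meta_path)
    return manifest
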