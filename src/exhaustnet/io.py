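"""File formats, run manifests and serialization for the pipeline.

All tabular files are tab-separated, UTF-8, no quoting, with "NA" (or ".")
for missing values. Motif and probe positions are 0-based half-open
throughout. Every writer emits rows in a deterministic (sorted) order so a
rerun from the same inputs, config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .diffprize import DifferentialRecord, FeatureMeasurement, PrizeMap
from .interactome import (
    DUMMY,
    Interaction,
    Interactome,
    INTERACTION_KINDS,
    assemble,
    compute_costs,
)
from .pbm import ProbeDesign, RecruitmentProfile, TFBindingModel
from .pcsf import Forest, PCSFConfig

__all__ = [
    "SchemaError",
    "read_feature_table",
    "write_prizes",
    "read_prizes",
    "read_edge_list",
    "write_edge_list",
    "write_forest",
    "read_forest",
    "read_probe_design",
    "write_probe_design",
    "read_measurements",
    "write_measurements",
    "write_models",
    "read_models",
    "write_meme",
    "write_profile",
    "write_contrast",
    "run_manifest",
    "read_manifest",
    "file_digest",
]

MISSING = {"NA", ".", ""}


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require(df: pd.DataFrame, columns: Sequence[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")


def read_feature_table(
    path: str | Path,
) -> list[FeatureMeasurement] | list[DifferentialRecord]:
    """Read a feature table in wide (replicate abundances) or long
    (precomputed differential) form, detected from the header.

    Wide: ``feature_id``, ``layer``, then one column per condition-replicate
    named ``<condition>_<replicate>`` (e.g. ``rest_1``, ``stim_3``). Long:
    ``feature_id``, ``timepoint``, ``log2_fc``, ``fdr``. Rows with missing
    abundances are excluded from testing; duplicate identities are an error.
    """
    df = _read_tsv(path)
    if "log2_fc" in df.columns:
        _require(df, ["feature_id", "timepoint", "log2_fc", "fdr"], path)
        if df.duplicated(["feature_id", "timepoint"]).any():
            raise SchemaError(f"{path}: duplicate feature_id+timepoint rows")
        records = []
        for i, row in df.iterrows():
            try:
                records.append(
                    DifferentialRecord(
                        feature_id=row["feature_id"],
                        timepoint=row["timepoint"],
                        log2_fc=float(row["log2_fc"]),
                        fdr=float(row["fdr"]),
                        layer=row.get("layer", "protein")
                        if "layer" in df.columns
                        else "protein",
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"{path}: line {i + 2}: {exc}") from exc
        return records

    _require(df, ["feature_id", "layer"], path)
    value_cols = [c for c in df.columns if c not in ("feature_id", "layer")]
    if not value_cols:
        raise SchemaError(f"{path}: no condition_replicate columns found")
    if df.duplicated(["feature_id", "layer"]).any():
        raise SchemaError(f"{path}: duplicate feature_id+layer rows")
    measurements: list[FeatureMeasurement] = []
    for i, row in df.iterrows():
        per_cond: dict[str, list[float]] = {}
        for col in value_cols:
            if "_" not in col:
                raise SchemaError(
                    f"{path}: column {col!r} is not <condition>_<replicate>"
                )
            cond = col.rsplit("_", 1)[0]
            raw = row[col].strip()
            if raw in MISSING:
                continue  # missing replicate: excluded from testing
            try:
                per_cond.setdefault(cond, []).append(float(raw))
            except ValueError as exc:
                raise SchemaError(
                    f"{path}: line {i + 2}: non-numeric abundance {raw!r} in {col}"
                ) from exc
        for cond, vals in per_cond.items():
            try:
                measurements.append(
                    FeatureMeasurement(
                        row["feature_id"], cond, tuple(vals), layer=row["layer"]
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"{path}: line {i + 2}: {exc}") from exc
    return measurements


def write_prizes(pm: PrizeMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\tprize\n")
        for node in sorted(pm.prizes):
            fh.write(f"{node}\t{pm.prizes[node]:.10g}\n")


def read_prizes(path: str | Path, timepoint: str = "") -> PrizeMap:
    df = _read_tsv(path)
    _require(df, ["node_id", "prize"], path)
    return PrizeMap(
        prizes={r["node_id"]: float(r["prize"]) for _, r in df.iterrows()},
        timepoint=timepoint,
    )


def read_edge_list(path: str | Path, fmt: str = "auto") -> list[Interaction]:
    """Read interactions from TSV (header: source, target, kind[, provenance])
    or SIF (``source kind target``, no header)."""
    path = Path(path)
    if fmt == "auto":
        first = path.read_text(encoding="utf-8").splitlines()[:1]
        header = first[0].split("\t") if first else []
        fmt = "tsv" if "source" in header and "target" in header else "sif"
    if fmt == "tsv":
        df = _read_tsv(path)
        _require(df, ["source", "target"], path)
        return [
            Interaction(
                r["source"],
                r["target"],
                r.get("kind", "other") if "kind" in df.columns else "other",
                r.get("provenance", "") if "provenance" in df.columns else "",
            )
            for _, r in df.iterrows()
        ]
    if fmt == "sif":
        out = []
        for ln, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise SchemaError(f"{path}: line {ln}: SIF needs 'source kind target'")
            src, kind, tgt = parts
            if kind not in INTERACTION_KINDS:
                kind = "other"
            out.append(Interaction(src, tgt, kind))
        return out
    raise ValueError(f"unknown edge-list format {fmt!r}")


def write_edge_list(g: Interactome, path: str | Path) -> None:
    """Weighted edge TSV with w and c columns."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tkind\tprovenance\tw\tc\n")
        for u, v in sorted(g.graph.edges):
            d = g.graph.edges[u, v]
            fh.write(
                f"{u}\t{v}\t{d.get('kind', 'other')}\t{d.get('provenance', '')}\t"
                f"{d.get('w', float('nan')):.12g}\t{d.get('c', float('nan')):.12g}\n"
            )


def _forest_graph(forest: Forest, g: Interactome, prizes: PrizeMap) -> nx.DiGraph:
    h = nx.DiGraph()
    for v in sorted(forest.real_nodes):
        h.add_node(
            v,
            prize=float(prizes.get(v)),
            depth=int(forest.depths.get(v, -1)),
            root=bool(v in forest.roots),
            tree_id=str(forest.tree_id.get(v, "")),
        )
    for u, v in sorted(forest.real_edges):
        h.add_edge(u, v, cost=float(g.cost(u, v)))
    return h


def write_forest(
    forest: Forest,
    g: Interactome,
    prizes: PrizeMap,
    path_graphml: str | Path,
    path_tsv: str | Path,
) -> None:
    """GraphML + flat TSV (edge list followed by a node table)."""
    h = _forest_graph(forest, g, prizes)
    nx.write_graphml(h, path_graphml, named_key_ids=True, edge_id_from_attribute=None)
    with open(path_tsv, "w", encoding="utf-8") as fh:
        fh.write("record\tu\tv\tcost\tprize\tdepth\troot\ttree_id\n")
        for u, v in sorted(forest.real_edges):
            fh.write(f"edge\t{u}\t{v}\t{g.cost(u, v):.12g}\tNA\tNA\tNA\tNA\n")
        for v in sorted(forest.real_nodes):
            fh.write(
                f"node\t{v}\tNA\tNA\t{prizes.get(v):.12g}\t"
                f"{forest.depths.get(v, -1)}\t{int(v in forest.roots)}\t"
                f"{forest.tree_id.get(v, '')}\n"
            )


def read_forest(path_tsv: str | Path) -> Forest:
    df = _read_tsv(path_tsv)
    _require(df, ["record", "u", "v", "depth", "root", "tree_id"], path_tsv)
    edges = set()
    nodes = set()
    depths: dict[str, int] = {}
    tree_id: dict[str, str] = {}
    roots = []
    for _, r in df.iterrows():
        if r["record"] == "edge":
            edges.add((r["u"], r["v"]))
            nodes.update((r["u"], r["v"]))
        else:
            v = r["u"]
            nodes.add(v)
            depths[v] = int(r["depth"])
            tree_id[v] = r["tree_id"]
            if r["root"] == "1":
                roots.append(v)
    roots = tuple(sorted(roots))
    return Forest(
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        roots=roots,
        kappa=len(roots),
        depths=depths,
        tree_id=tree_id,
    )


def write_probe_design(design: Iterable[ProbeDesign], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tprobe_class\tmodel_id\tsv_position\tsv_base\tsequence\n")
        for p in sorted(design, key=lambda p: p.probe_id):
            fh.write(
                f"{p.probe_id}\t{p.probe_class}\t{p.model_id or 'NA'}\t"
                f"{p.sv_position if p.sv_position is not None else 'NA'}\t"
                f"{p.sv_base or 'NA'}\t{p.sequence}\n"
            )


def read_probe_design(path: str | Path) -> list[ProbeDesign]:
    df = _read_tsv(path)
    _require(df, ["probe_id", "probe_class", "model_id", "sequence"], path)
    out = []
    for _, r in df.iterrows():
        out.append(
            ProbeDesign(
                probe_id=r["probe_id"],
                sequence=r["sequence"],
                probe_class=r["probe_class"],
                model_id=None if r["model_id"] in MISSING else r["model_id"],
                sv_position=None
                if r.get("sv_position", "NA") in MISSING
                else int(r["sv_position"]),
                sv_base=None if r.get("sv_base", "NA") in MISSING else r["sv_base"],
            )
        )
    return out


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["probe_id", "replicate", "condition", "cofactor", "fluorescence"]
    df = df[cols].sort_values(cols[:4], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, ["probe_id", "replicate", "condition", "cofactor", "fluorescence"], path)
    df["fluorescence"] = df["fluorescence"].astype(float)
    return df


def write_models(models: Iterable[TFBindingModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("model_id\tconsensus\tfamily\n")
        for m in sorted(models, key=lambda m: m.model_id):
            fh.write(f"{m.model_id}\t{m.consensus}\t{m.family}\n")


def read_models(path: str | Path) -> list[TFBindingModel]:
    df = _read_tsv(path)
    _require(df, ["model_id", "consensus", "family"], path)
    return [
        TFBindingModel(r["model_id"], r["consensus"], r["family"])
        for _, r in df.iterrows()
    ]


def write_meme(
    motifs: Sequence[tuple[str, np.ndarray]], path: str | Path, nsites: int = 20
) -> None:
    """MEME minimal motif format from (name, L x 4 probability matrix) pairs."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for name, probs in motifs:
            probs = np.asarray(probs, dtype=float)
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {probs.shape[0]} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def write_profile(profile: RecruitmentProfile, path: str | Path) -> None:
    """families x cofactors strength matrix per condition (long TSV)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cofactor\tfamily\tcondition\tstrength\tsupport\n")
        for key in sorted(profile.strengths):
            cof, fam, cond = key
            fh.write(
                f"{cof}\t{fam}\t{cond}\t{profile.strengths[key]:.10g}\t"
                f"{profile.support.get(key, 0)}\n"
            )


def write_contrast(contrast: pd.DataFrame, path: str | Path) -> None:
    contrast.to_csv(path, sep="\t", index=False, float_format="%.10g")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in sorted(obj) if not isinstance(obj, (list, tuple))] \
            if isinstance(obj, (set, frozenset)) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_manifest(
    config: PCSFConfig | Mapping,
    seed: int,
    path: str | Path,
    objective: float | None = None,
    inputs: Mapping[str, str | Path] | None = None,
    extra: Mapping | None = None,
) -> dict:
    """Write a JSON run manifest: config, seed, objective, input digests.

    Two runs with identical manifests (same config, seed and input digests)
    produce byte-identical outputs.
    """
    manifest = {
        "config": _jsonable(config),
        "seed": int(seed),
        "objective": None if objective is None else float(objective),
        "inputs": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in (inputs or {}).items()
        },
    }
    if extra:
        manifest["extra"] = _jsonable(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_manifest(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
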