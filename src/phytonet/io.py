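"""Readers and writers for the tabular inputs and analysis outputs.

Input tables are plain TSV with headers:

* ``plants.tsv`` — record_id, scientific_name, latin_name, use_target, category
* ``plant_chemical.tsv`` — plant_id, chemical_id
* ``predictions.tsv`` — chemical_id, target_id, probability
* ``annotations.tsv`` (optional) — chemical_id, kingdom, superclass, class,
  subclass, direct_parent

Networks round-trip through a node/edge TSV pair or GraphML; dendrograms
export to Newick with branch lengths chosen so that the root-to-leaf path
length equals the merge height (ultrametric tree).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import (
    Category,
    MultipartiteNetwork,
    PlantRecord,
    TargetPrediction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_plants",
    "read_pc_edges",
    "read_predictions",
    "read_annotations",
    "read_tables",
    "write_network_tsv",
    "read_network_tsv",
    "write_network_graphml",
    "read_network_graphml",
    "write_outputs",
    "linkage_to_newick",
]

NETWORK_FORMATS = ("tsv", "graphml")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_plants(path) -> list[PlantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df, ["record_id", "scientific_name", "latin_name", "use_target", "category"], path
    )
    records = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rid = str(row.record_id)
        if rid in seen:
            raise ValueError(f"{path}: duplicate record_id {rid!r} at line {i}")
        seen.add(rid)
        records.append(
            PlantRecord(
                record_id=rid,
                scientific_name=str(row.scientific_name).strip(),
                latin_name=str(row.latin_name).strip(),
                use_target=str(row.use_target).strip(),
                category=Category.coerce(row.category),
            )
        )
    return records


def read_pc_edges(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["plant_id", "chemical_id"], path)
    return list(zip(df["plant_id"].astype(str), df["chemical_id"].astype(str)))


def read_predictions(path) -> list[TargetPrediction]:
    """Load chemical-target activity predictions.

    Probabilities are validated to [0, 1] with a row-numbered error.
    Duplicate (chemical, target) pairs collapse to the maximum probability —
    the most permissive reading compatible with a "probability above the
    cut-off" interaction rule.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probability": float}, keep_default_na=False)
    _require_columns(df, ["chemical_id", "target_id", "probability"], path)
    probs = df["probability"].to_numpy(dtype=float)
    bad = np.flatnonzero((probs < 0) | (probs > 1) | ~np.isfinite(probs))
    if bad.size:
        line = int(bad[0]) + 2  # header is line 1
        raise ValueError(
            f"{path}: probability {probs[bad[0]]!r} outside [0, 1] at line {line}"
        )
    best: dict[tuple[str, str], float] = {}
    for chem, tgt, p in zip(
        df["chemical_id"].astype(str), df["target_id"].astype(str), probs
    ):
        key = (chem, tgt)
        if key not in best or p > best[key]:
            best[key] = p
    if len(best) < len(df):
        logger.info(
            "collapsed %d duplicate (chemical, target) predictions to max probability",
            len(df) - len(best),
        )
    return [TargetPrediction(c, t, p) for (c, t), p in best.items()]


def read_annotations(path) -> pd.DataFrame:
    """Chemical classification annotations, indexed by chemical_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df, ["chemical_id", "kingdom", "superclass", "class", "subclass", "direct_parent"],
        path,
    )
    return df.set_index("chemical_id")


def read_tables(
    plants_path,
    pc_edges_path,
    predictions_path,
    annotations_path=None,
) -> tuple[list[PlantRecord], list[tuple[str, str]], list[TargetPrediction], Optional[pd.DataFrame]]:
    """Read all input tables at once; annotations are optional."""
    records = read_plants(plants_path)
    pc = read_pc_edges(pc_edges_path)
    preds = read_predictions(predictions_path)
    ann = read_annotations(annotations_path) if annotations_path else None
    return records, pc, preds, ann


# -- network round-trips ---------------------------------------------------


def write_network_tsv(net: MultipartiteNetwork, outdir) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = []
    for layer, ids in (
        ("plant", net.plants),
        ("chemical", net.chemicals),
        ("target", net.targets),
    ):
        for n in sorted(ids):
            nodes.append({"node_id": n, "layer": layer, **net.node_attrs.get(n, {})})
    nodes_path = outdir / "nodes.tsv"
    edges_path = outdir / "edges.tsv"
    pd.DataFrame(nodes).to_csv(nodes_path, sep="\t", index=False)
    edges = [{"source": p, "target": c, "kind": "plant-chemical"} for p, c in sorted(net.pc_edges)]
    edges += [{"source": c, "target": t, "kind": "chemical-target"} for c, t in sorted(net.ct_edges)]
    pd.DataFrame(edges, columns=["source", "target", "kind"]).to_csv(
        edges_path, sep="\t", index=False
    )
    return nodes_path, edges_path


def read_network_tsv(indir) -> MultipartiteNetwork:
    indir = Path(indir)
    nodes = pd.read_csv(indir / "nodes.tsv", sep="\t", dtype=str, keep_default_na=False)
    edges = pd.read_csv(indir / "edges.tsv", sep="\t", dtype=str, keep_default_na=False)
    layers: dict[str, set[str]] = {"plant": set(), "chemical": set(), "target": set()}
    attrs: dict[str, dict[str, object]] = {}
    extra_cols = [c for c in nodes.columns if c not in ("node_id", "layer")]
    for row in nodes.itertuples(index=False):
        layers[row.layer].add(row.node_id)
        extra = {c: getattr(row, c) for c in extra_cols if getattr(row, c) != ""}
        if extra:
            attrs[row.node_id] = extra
    pc, ct = [], []
    for row in edges.itertuples(index=False):
        if row.kind == "plant-chemical":
            pc.append((row.source, row.target))
        elif row.kind == "chemical-target":
            ct.append((row.source, row.target))
        else:
            raise ValueError(f"unknown edge kind {row.kind!r}")
    return MultipartiteNetwork(
        plants=layers["plant"],
        chemicals=layers["chemical"],
        targets=layers["target"],
        pc_edges=pc,
        ct_edges=ct,
        node_attrs=attrs,
    )


def write_network_graphml(net: MultipartiteNetwork, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net.to_networkx(), path)
    return path


def read_network_graphml(path) -> MultipartiteNetwork:
    g = nx.read_graphml(path)
    layers: dict[str, set[str]] = {"plant": set(), "chemical": set(), "target": set()}
    attrs: dict[str, dict[str, object]] = {}
    for n, data in g.nodes(data=True):
        layer = data.get("layer")
        if layer not in layers:
            raise ValueError(f"node {n!r} has unknown layer {layer!r}")
        layers[layer].add(n)
        extra = {k: v for k, v in data.items() if k != "layer"}
        if extra:
            attrs[n] = extra
    pc, ct = [], []
    for u, v in g.edges():
        lu, lv = g.nodes[u]["layer"], g.nodes[v]["layer"]
        if "chemical" == lu:
            u, v = v, u
            lu, lv = lv, lu
        if lv != "chemical":
            raise ValueError(f"edge ({u}, {v}) does not touch the chemical layer")
        if lu == "plant":
            pc.append((u, v))
        else:
            ct.append((v, u))
    return MultipartiteNetwork(
        plants=layers["plant"],
        chemicals=layers["chemical"],
        targets=layers["target"],
        pc_edges=pc,
        ct_edges=ct,
        node_attrs=attrs,
    )


def write_outputs(obj, path, format: str):
    """Dispatch writer: networks to 'tsv'/'graphml', dendrograms to 'newick'.

    Raises ValueError listing supported formats for anything else.
    """
    from .hcluster import PlantDendrogram  # local import avoids a cycle

    if isinstance(obj, MultipartiteNetwork):
        if format == "tsv":
            return write_network_tsv(obj, path)
        if format == "graphml":
            return write_network_graphml(obj, path)
        raise ValueError(
            f"unsupported network format {format!r}; supported: {list(NETWORK_FORMATS)}"
        )
    if isinstance(obj, PlantDendrogram):
        if format == "newick":
            path = Path(path)
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text(obj.to_newick() + "\n")
            return path
        raise ValueError(f"unsupported dendrogram format {format!r}; supported: ['newick']")
    if isinstance(obj, pd.DataFrame):
        if format == "tsv":
            path = Path(path)
            path.parent.mkdir(parents=True, exist_ok=True)
            obj.to_csv(path, sep="\t", index=False)
            return path
        raise ValueError(f"unsupported table format {format!r}; supported: ['tsv']")
    raise ValueError(f"no writer for object of type {type(obj).__name__}")


# -- dendrogram export -----------------------------------------------------


def linkage_to_newick(Z: np.ndarray, leaves: Sequence[str]) -> str:
    """Convert a scipy linkage matrix to a Newick string.

    Branch lengths are assigned so the path length from the root to any leaf
    equals the root merge height: each child's branch is the parent height
    minus the child's own merge height (leaves have height 0), giving an
    ultrametric tree whose node depths are the complete-linkage merge
    distances.
    """
    n = len(leaves)
    if n == 0:
        raise ValueError("cannot export an empty dendrogram")
    if n == 1:
        return f"{leaves[0]};"
    heights = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h, _size) in enumerate(Z):
        node = n + k
        children[node] = (int(a), int(b))
        heights[node] = float(h)

    def render(node: int, parent_h: float) -> str:
        length = parent_h - heights[node]
        if node < n:
            return f"{leaves[node]}:{length:.10g}"
        a, b = children[node]
        h = heights[node]
        return f"({render(a, h)},{render(b, h)}):{length:.10g}"

    root = n + len(Z) - 1
    a, b = children[root]
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"
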