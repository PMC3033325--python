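"""Serialization of forests and imputed latent data.

Forests round-trip losslessly (structure, layers, cardinalities and CPT
entries) through JSON and GraphML; DOT is write-only, intended for graph
viewers.  Imputed latent-variable matrices are written as TSV with one
column per latent variable and one row per individual.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forest import Forest

DIALECTS = ("graphml", "json", "dot")


def write_forest(forest: Forest, path, dialect: str = "json") -> None:
    path = Path(path)
    if dialect == "json":
        path.write_text(forest.to_json())
    elif dialect == "graphml":
        _write_graphml(forest, path)
    elif dialect == "dot":
        _write_dot(forest, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")


def read_forest(path, dialect: str | None = None) -> Forest:
    path = Path(path)
    if dialect is None:
        dialect = "graphml" if path.suffix == ".graphml" else "json"
    if dialect == "json":
        return Forest.from_json(path.read_text())
    if dialect == "graphml":
        return _read_graphml(path)
    raise ValueError(f"cannot read dialect {dialect!r}")


def _write_graphml(forest: Forest, path) -> None:
    import networkx as nx

    g = forest.to_networkx()
    for nid in g.nodes:
        # parameters stored as JSON strings: GraphML has no array attributes,
        # and json round-trips Python floats exactly (repr-based)
        if nid in forest.priors:
            g.nodes[nid]["prior"] = json.dumps(forest.priors[nid].tolist())
        if nid in forest.cpts:
            g.nodes[nid]["cpt"] = json.dumps(forest.cpts[nid].tolist())
        g.nodes[nid]["order"] = (forest.observed_ids.index(nid)
                                 if nid in forest.observed_ids
                                 else -1 - forest.latent_ids.index(nid))
        if forest.imputed is not None and nid in forest.imputed.columns:
            g.nodes[nid]["imputed"] = json.dumps(
                forest.imputed[nid].tolist())
    nx.write_graphml(g, str(path))


def _read_graphml(path) -> Forest:
    import networkx as nx

    g = nx.read_graphml(str(path))
    f = Forest()
    observed, latent = [], []
    imputed: dict[str, list[int]] = {}
    for nid, attrs in g.nodes(data=True):
        from .forest import Node

        window = attrs.get("window", -1)
        f.nodes[nid] = Node(nid, int(attrs["layer"]), int(attrs["cardinality"]),
                            bool(attrs["is_latent"]),
                            None if window == -1 else int(window))
        f.children[nid] = []
        if "prior" in attrs:
            f.priors[nid] = np.asarray(json.loads(attrs["prior"]))
        if "cpt" in attrs:
            f.cpts[nid] = np.asarray(json.loads(attrs["cpt"]))
        if "imputed" in attrs:
            imputed[nid] = json.loads(attrs["imputed"])
        order = int(attrs["order"])
        if attrs["is_latent"]:
            latent.append((-1 - order, nid))
        else:
            observed.append((order, nid))
    for pid, cid in g.edges:
        f.parent[cid] = pid
        f.children[pid].append(cid)
    f.observed_ids = [nid for _, nid in sorted(observed)]
    f.latent_ids = [nid for _, nid in sorted(latent)]
    # restore the children order used by the builder (creation order)
    for pid in f.children:
        f.children[pid].sort(key=lambda c: _node_order(f, c))
    if imputed:
        f.imputed = pd.DataFrame(
            {nid: np.asarray(imputed[nid], dtype=np.int64)
             for nid in f.latent_ids})
    return f


def _node_order(f: Forest, nid: str):
    if nid in f.observed_ids:
        return (0, f.observed_ids.index(nid))
    return (1, f.latent_ids.index(nid))


def _write_dot(forest: Forest, path) -> None:
    lines = ["digraph fhlcm {"]
    for nid, node in forest.nodes.items():
        shape = "box" if node.is_latent else "ellipse"
        lines.append(
            f'  "{nid}" [shape={shape}, label="{nid}\\ncard={node.cardinality}"];')
    for cid, pid in forest.parent.items():
        lines.append(f'  "{pid}" -> "{cid}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_imputed(forest: Forest, path) -> None:
    """TSV of imputed latent values: one column per latent variable."""
    if forest.latent_ids and (forest.imputed is None
                              or list(forest.imputed.columns) != forest.latent_ids):
        raise ValueError("imputed columns do not match the forest's latent list")
    if forest.imputed is None:
        Path(path).write_text("\t".join(forest.latent_ids) + "\n")
        return
    forest.imputed.to_csv(path, sep="\t", index=False)


def read_imputed(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=np.int64)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
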