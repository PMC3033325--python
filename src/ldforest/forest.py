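"""The forest of hierarchical latent class models (FHLCM).

A directed forest over observed SNPs (layer 0) and latent variables
(layer >= 1): every node has at most one parent, edges point from a latent
variable to the variables it subsumes, and each connected component is a
tree.  Roots carry prior distributions; non-roots carry conditional
probability tables given their parent.  The forest also stores the imputed
per-individual values of every latent variable, which double as the data
columns of higher layers during construction.

Latent variables are named ``H<layer>_<index>``, where the index enumerates
latent variables within a layer across the whole forest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel used in serialized MRCA matrices for cross-tree pairs
DIFFERENT_TREES = "N"


@dataclass
class Node:
    id: str
    layer: int
    cardinality: int
    is_latent: bool
    window: int | None = None


@dataclass
class Forest:
    """Directed forest over observed + latent variables with CPT parameters."""

    nodes: dict[str, Node] = field(default_factory=dict)
    parent: dict[str, str] = field(default_factory=dict)       # child -> parent
    children: dict[str, list[str]] = field(default_factory=dict)
    priors: dict[str, np.ndarray] = field(default_factory=dict)  # roots only
    cpts: dict[str, np.ndarray] = field(default_factory=dict)    # non-roots
    observed_ids: list[str] = field(default_factory=list)
    latent_ids: list[str] = field(default_factory=list)
    imputed: pd.DataFrame | None = None  # n × len(latent_ids)

    # -- construction ------------------------------------------------------

    def add_observed(self, node_id: str, cardinality: int,
                     window: int | None = None,
                     prior: np.ndarray | None = None) -> None:
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id!r}")
        self.nodes[node_id] = Node(node_id, 0, cardinality, False, window)
        self.children[node_id] = []
        self.observed_ids.append(node_id)
        if prior is not None:
            self.priors[node_id] = np.asarray(prior, dtype=float)

    def add_latent(self, node_id: str, cardinality: int, child_ids: list[str],
                   prior: np.ndarray, child_cpts: list[np.ndarray],
                   imputed_values: np.ndarray,
                   window: int | None = None) -> None:
        """Graft a validated latent class model onto the forest.

        The new latent node becomes the parent of ``child_ids``; the
        children's priors (they were roots) are replaced by their CPTs
        conditional on the latent variable.
        """
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id!r}")
        for cid in child_ids:
            if cid not in self.nodes:
                raise ValueError(f"unknown child {cid!r}")
            if cid in self.parent:
                raise ValueError(f"{cid!r} already has a parent")
        layer = 1 + max(self.nodes[c].layer for c in child_ids)
        self.nodes[node_id] = Node(node_id, layer, cardinality, True, window)
        self.children[node_id] = list(child_ids)
        self.priors[node_id] = np.asarray(prior, dtype=float)
        for cid, cpt in zip(child_ids, child_cpts):
            self.parent[cid] = node_id
            self.priors.pop(cid, None)
            self.cpts[cid] = np.asarray(cpt, dtype=float)
        self.latent_ids.append(node_id)
        col = pd.DataFrame({node_id: np.asarray(imputed_values, dtype=np.int64)})
        self.imputed = col if self.imputed is None else pd.concat(
            [self.imputed, col], axis=1)

    def next_latent_name(self, layer: int) -> str:
        count = sum(1 for nid in self.latent_ids
                    if self.nodes[nid].layer == layer)
        return f"H{layer}_{count + 1}"

    # -- queries -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def roots(self) -> list[str]:
        return [nid for nid in self.nodes if nid not in self.parent]

    def tree_count(self) -> int:
        return len(self.roots())

    def root_of(self, node_id: str) -> str:
        while node_id in self.parent:
            node_id = self.parent[node_id]
        return node_id

    def ancestors(self, node_id: str) -> list[str]:
        """Path from ``node_id`` (inclusive) up to its root."""
        path = [node_id]
        while path[-1] in self.parent:
            path.append(self.parent[path[-1]])
        return path

    def leaves_of(self, node_id: str) -> list[str]:
        """Observed descendants of ``node_id`` (itself, if observed)."""
        if not self.nodes[node_id].is_latent:
            return [node_id]
        out: list[str] = []
        stack = list(self.children[node_id])
        while stack:
            nid = stack.pop()
            if self.nodes[nid].is_latent:
                stack.extend(self.children[nid])
            else:
                out.append(nid)
        return sorted(out, key=self.observed_ids.index)

    def max_layer(self) -> int:
        return max(node.layer for node in self.nodes.values())

    def validate(self) -> None:
        """Assert the structural forest invariants."""
        for cid, pid in self.parent.items():
            if cid not in self.children.get(pid, []):
                raise AssertionError("parent/children maps inconsistent")
        for nid, node in self.nodes.items():
            if node.is_latent:
                kids = self.children[nid]
                if len(kids) < 2:
                    raise AssertionError(f"latent {nid} has <2 children")
                if node.layer != 1 + max(self.nodes[c].layer for c in kids):
                    raise AssertionError(f"bad layer for {nid}")
            elif node.layer != 0:
                raise AssertionError(f"observed {nid} not on layer 0")
            if nid in self.ancestors(nid)[1:]:
                raise AssertionError("cycle detected")

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for nid, node in self.nodes.items():
            g.add_node(nid, layer=node.layer, cardinality=node.cardinality,
                       is_latent=node.is_latent,
                       window=-1 if node.window is None else node.window)
        for cid, pid in self.parent.items():
            g.add_edge(pid, cid)
        return g

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"id": n.id, "layer": n.layer, "cardinality": n.cardinality,
                 "is_latent": n.is_latent, "window": n.window}
                for n in self.nodes.values()
            ],
            "edges": [[pid, cid] for cid, pid in self.parent.items()],
            "observed_ids": self.observed_ids,
            "latent_ids": self.latent_ids,
            "priors": {k: v.tolist() for k, v in self.priors.items()},
            "cpts": {k: v.tolist() for k, v in self.cpts.items()},
            "children": {k: v for k, v in self.children.items()},
            "imputed": (None if self.imputed is None
                        else self.imputed.to_dict(orient="list")),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Forest":
        f = cls()
        for nd in d["nodes"]:
            f.nodes[nd["id"]] = Node(nd["id"], nd["layer"], nd["cardinality"],
                                     nd["is_latent"], nd["window"])
        f.parent = {cid: pid for pid, cid in d["edges"]}
        f.children = {k: list(v) for k, v in d["children"].items()}
        f.observed_ids = list(d["observed_ids"])
        f.latent_ids = list(d["latent_ids"])
        f.priors = {k: np.asarray(v, dtype=float)
                    for k, v in d["priors"].items()}
        f.cpts = {k: np.asarray(v, dtype=float) for k, v in d["cpts"].items()}
        if d.get("imputed"):
            f.imputed = pd.DataFrame(
                {k: np.asarray(v, dtype=np.int64)
                 for k, v in d["imputed"].items()})[f.latent_ids]
        return f

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Forest":
        return cls.from_dict(json.loads(text))
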