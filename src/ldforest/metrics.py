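"""Evaluation statistics for a learned forest.

- DRR (dimension reduction rate): forest roots / number of SNPs — the
  fraction of variables left after each tree is synthesized by its root.
- ECR (entropy compression rate): sum of per-cluster joint entropies over
  the sum of marginal SNP entropies; <= 1 by subadditivity, and lower when
  clusters group genuinely dependent SNPs.
- MRCA level matrix: for every SNP pair in the same tree, the layer of their
  lowest common ancestor; a structural proxy for LD strength.
- Haplotype diversity: size of the smallest set of observed leaf-value
  tuples covering a given fraction of the sample.
- Layer statistics: variable counts and mean scaled MI of edges per layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SnpMatrix
from .forest import Forest
from .info import entropy, scaled_mutual_information

#: integer sentinel for SNP pairs that belong to different trees
SENTINEL = -1


@dataclass
class MrcaMatrix:
    """p×p matrix of MRCA layers; ``SENTINEL`` marks cross-tree pairs."""

    levels: np.ndarray
    marker_names: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels, index=self.marker_names,
                          columns=self.marker_names, dtype=object)
        return df.mask(df == SENTINEL, "N")


def dimension_reduction_rate(forest: Forest) -> float:
    """Number of roots divided by the number of observed SNPs."""
    p = len(forest.observed_ids)
    if p == 0:
        raise ValueError("forest has no observed variables")
    return forest.tree_count() / p


def joint_entropy(data: np.ndarray) -> float:
    """Plug-in entropy of the rows of ``data`` treated as value tuples."""
    data = np.asarray(data)
    if data.ndim == 1:
        data = data[:, None]
    _, counts = np.unique(data, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_compression_rate(grouping: list[list[str]],
                             matrix: SnpMatrix) -> float:
    """Sum of cluster joint entropies / sum of marginal SNP entropies."""
    col = {name: j for j, name in enumerate(matrix.marker_names)}
    covered = [name for cluster in grouping for name in cluster]
    if sorted(covered) != sorted(matrix.marker_names):
        raise ValueError("grouping must cover every SNP exactly once")
    marginal = sum(entropy(matrix.values[:, j]) for j in range(matrix.p))
    if marginal <= 0:
        raise ValueError("all SNPs constant: ECR undefined")
    block = sum(
        joint_entropy(matrix.values[:, [col[name] for name in cluster]])
        for cluster in grouping)
    return block / marginal


def forest_grouping(forest: Forest) -> list[list[str]]:
    """The SNP partition induced by the forest: leaves per tree."""
    return [forest.leaves_of(r) for r in forest.roots()]


def tree_count(forest: Forest) -> int:
    """Number of connected components (= roots)."""
    return forest.tree_count()


def mrca_levels(forest: Forest) -> MrcaMatrix:
    """Layer of the lowest common ancestor for every observed SNP pair."""
    names = forest.observed_ids
    p = len(names)
    paths = {name: forest.ancestors(name) for name in names}
    depth = {name: {nid: k for k, nid in enumerate(path)}
             for name, path in paths.items()}
    levels = np.zeros((p, p), dtype=np.int64)
    for i in range(p):
        for j in range(i + 1, p):
            di = depth[names[i]]
            lca = next((nid for nid in paths[names[j]] if nid in di), None)
            lev = SENTINEL if lca is None else forest.nodes[lca].layer
            levels[i, j] = levels[j, i] = lev
    return MrcaMatrix(levels, list(names))


def most_common_haplotypes(subtree_leaf_data, coverage: float = 0.75) -> int:
    """Minimal number of distinct leaf-value tuples covering ``coverage``.

    Tuples are ranked by descending frequency, ties broken lexicographically
    on the tuple values.
    """
    data = np.asarray(subtree_leaf_data)
    if data.size == 0:
        raise ValueError("empty data")
    if data.ndim == 1:
        data = data[:, None]
    uniq, counts = np.unique(data, axis=0, return_counts=True)
    order = sorted(range(len(counts)),
                   key=lambda k: (-counts[k], tuple(uniq[k])))
    freq = counts[order] / counts.sum()
    cum = np.cumsum(freq)
    return int(np.searchsorted(cum, coverage - 1e-12) + 1)


def layer_statistics(forest: Forest, matrix: SnpMatrix) -> pd.DataFrame:
    """Per layer: number of variables and mean scaled MI of incoming edges.

    The scaled MI of an edge H→X is computed between the imputed values of H
    and the data column of X (observed data for SNPs, imputed values for
    latent children).
    """
    col = {name: matrix.values[:, j]
           for j, name in enumerate(matrix.marker_names)}
    if forest.imputed is not None:
        for name in forest.imputed.columns:
            col[name] = forest.imputed[name].to_numpy()
    rows = []
    for layer in range(forest.max_layer() + 1):
        ids = [nid for nid, node in forest.nodes.items() if node.layer == layer]
        smis = []
        for nid in ids:
            if not forest.nodes[nid].is_latent:
                continue
            for child in forest.children[nid]:
                smis.append(scaled_mutual_information(col[nid], col[child]))
        rows.append({"layer": layer, "n_variables": len(ids),
                     "mean_scaled_mi": float(np.mean(smis)) if smis else np.nan})
    return pd.DataFrame(rows)


def median_r2_by_mrca_level(forest: Forest, matrix: SnpMatrix) -> pd.Series:
    """Median pairwise r² grouped by MRCA level (cross-tree pairs under 'N')."""
    from .info import r_squared

    mm = mrca_levels(forest)
    names = mm.marker_names
    col = {name: matrix.values[:, j]
           for j, name in enumerate(matrix.marker_names)}
    buckets: dict[object, list[float]] = {}
    for i in range(len(names)):
        xi = col[names[i]]
        if np.ptp(xi) == 0:
            continue
        for j in range(i + 1, len(names)):
            xj = col[names[j]]
            if np.ptp(xj) == 0:
                continue
            lev = mm.levels[i, j]
            key = "N" if lev == SENTINEL else int(lev)
            buckets.setdefault(key, []).append(r_squared(xi, xj))
    keys = sorted((k for k in buckets if k != "N")) + (
        ["N"] if "N" in buckets else [])
    return pd.Series({k: float(np.median(buckets[k])) for k in keys})
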