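"""Construction of the forest of hierarchical latent class models.

The construction splits the marker sequence into contiguous windows and, per
window, runs an agglomerative loop: compute the pairwise MI matrix over the
current working set (observed SNPs plus previously imputed latent columns),
binarize it at a quantile threshold, partition with CAST, and for each
cluster of two or more variables fit a latent class model by EM, impute the
latent column, and validate it against the information-decay criterion C.
Validated latent variables replace their children in the working set; nodes
of rejected clusters stay isolated and re-enter partitioning at the next
step.  The loop stops when the partition is all singletons or no cluster
validates.  Per-window forests are disjoint (no edge crosses a window), so
the final model is their union and its joint distribution the product of the
per-window factors.

Windows are processed one at a time; only the current window's columns and
working set are held alongside the input matrix, so peak memory beyond the
input is O(n·s) for window size s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cast import binarize, cast
from .data import Coding, SnpMatrix
from .forest import Forest
from .info import mi_quantile_threshold, pairwise_mi_matrix
from .lcm import EmConfig, criterion_c, em_learn, impute, latent_cardinality


@dataclass
class CfhlcConfig:
    """Tuning parameters of the construction.

    Defaults are the reference parameter set: a=0.2, b=2, card_max=20,
    t_cast=0.95, t_MI = 0.95-quantile of the MI matrix, t=0.3, window
    size 100.
    """

    window_size: int = 100
    t: float = 0.3                 # information-dilution threshold on C
    a: float = 0.2                 # affine cardinality slope
    b: float = 2.0                 # affine cardinality intercept
    card_max: int = 20             # latent cardinality cap
    t_cast: float = 0.95           # CAST affinity threshold
    mi_quantile: float = 0.95      # quantile defining t_MI
    t_mi_policy: str = "step"      # "step": t_MI recomputed from each step's
                                   # working-set MI matrix; "window": fixed
                                   # per window from the layer-0 matrix
    imputation_mode: str = "map"   # "map" or "sample"
    em: EmConfig = field(default_factory=EmConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window size must be >= 2")
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("t must lie in [0, 1]")
        if self.t_mi_policy not in ("window", "step"):
            raise ValueError("t_mi_policy must be 'window' or 'step'")
        if isinstance(self.em, dict):
            self.em = EmConfig(**self.em)


@dataclass
class _WorkingVar:
    """One variable of a window's current working set."""

    id: str
    column: np.ndarray
    cardinality: int
    layer: int


def split_windows(p: int, s: int) -> list[range]:
    """Contiguous column windows of size ``s``; the last holds the remainder."""
    if s < 2:
        raise ValueError("window size must be >= 2")
    if p < 1:
        raise ValueError("empty matrix")
    return [range(lo, min(lo + s, p)) for lo in range(0, p, s)]


def build_window(matrix: SnpMatrix, window: range, window_index: int,
                 config: CfhlcConfig, forest: Forest,
                 seed_seq: np.random.SeedSequence) -> dict:
    """Run the agglomerative loop on one window, grafting onto ``forest``.

    Returns a diagnostics dict (steps run, latent variables created and
    clusters rejected).
    """
    work = [
        _WorkingVar(matrix.marker_names[j], matrix.values[:, j],
                    matrix.coding.cardinality, 0)
        for j in window
    ]
    for var in work:
        counts = np.bincount(var.column, minlength=var.cardinality)
        forest.add_observed(var.id, var.cardinality, window_index,
                            prior=counts / counts.sum())
    diag = {"window": window_index, "n_markers": len(work), "steps": 0,
            "n_latent": 0, "n_rejected": 0}
    if len(work) < 2:
        return diag

    step = 0
    t_mi: float | None = None
    while len(work) >= 2:
        step_seq = seed_seq.spawn(1)[0]
        cols = np.column_stack([v.column for v in work])
        mi = pairwise_mi_matrix(cols, variable_ids=[v.id for v in work])
        if t_mi is None or config.t_mi_policy == "step":
            # "window" policy instead holds the layer-0 quantile fixed for
            # the whole window, so the similarity bar never drops as the
            # working set shrinks
            t_mi = mi_quantile_threshold(mi, config.mi_quantile)
        sim = binarize(mi, t_mi)
        clusters = cast(sim, config.t_cast)
        diag["steps"] = step + 1
        if all(len(c) == 1 for c in clusters):
            break

        by_id = {v.id: v for v in work}
        n_valid = 0
        cluster_seqs = step_seq.spawn(len(clusters))
        for cluster, cseq in zip(clusters, cluster_seqs):
            if len(cluster) < 2:
                continue
            members = [by_id[cid] for cid in cluster]
            card = latent_cardinality(len(cluster), config.a, config.b,
                                      config.card_max)
            child_data = np.column_stack([m.column for m in members])
            em_seed, imp_seed = cseq.spawn(2)
            name = forest.next_latent_name(
                1 + max(m.layer for m in members))
            model = em_learn(child_data, card, config.em, seed=em_seed,
                             child_ids=cluster,
                             child_cards=[m.cardinality for m in members],
                             latent_id=name)
            latent_values = impute(model, child_data,
                                   mode=config.imputation_mode, seed=imp_seed)
            c_value = criterion_c(model, child_data, latent_values)
            if c_value >= config.t:
                forest.add_latent(name, card, cluster, model.prior,
                                  model.child_cpts, latent_values,
                                  window=window_index)
                new_layer = forest.nodes[name].layer
                work = ([v for v in work if v.id not in set(cluster)]
                        + [_WorkingVar(name, latent_values, card, new_layer)])
                by_id = {v.id: v for v in work}
                n_valid += 1
                diag["n_latent"] += 1
            else:
                diag["n_rejected"] += 1
        if n_valid == 0:
            break
        step += 1
    return diag


def cfhlc(matrix: SnpMatrix, config: CfhlcConfig | None = None) -> tuple[Forest, list[dict]]:
    """Build the full forest: windowing, per-window loops, union.

    Returns the forest and per-window diagnostics.  Fully reproducible given
    ``config.seed``: per-window, per-step and per-cluster sub-seeds are
    derived deterministically from the master seed.
    """
    config = config or CfhlcConfig()
    if matrix.has_missing:
        matrix = matrix.fill_missing()
    windows = split_windows(matrix.p, config.window_size)
    master = np.random.SeedSequence(config.seed)
    window_seqs = master.spawn(len(windows))
    forest = Forest()
    diagnostics = []
    for i, (window, wseq) in enumerate(zip(windows, window_seqs)):
        diagnostics.append(build_window(matrix, window, i, config, forest, wseq))
    forest.validate()
    return forest, diagnostics
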