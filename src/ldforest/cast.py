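"""CAST clique partitioning over a binarized mutual-information graph.

CAST (cluster affinity search technique) builds clusters one at a time from
a 0/1 similarity matrix: it opens a cluster on a high-degree seed, then
alternates between adding the unassigned element of highest affinity to the
open cluster and removing the member of lowest affinity, under the affinity
threshold ``t_cast``, until the cluster stabilizes and is closed.  Applied
here to partition SNPs / latent variables into non-overlapping clusters of
mutually dependent variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .info import MiMatrix


@dataclass
class BinarySimilarity:
    """Symmetric 0/1 similarity matrix with unit diagonal."""

    values: np.ndarray
    variable_ids: list

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not (v == v.T).all():
            raise ValueError("similarity matrix must be symmetric")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("similarity entries must be 0 or 1")
        np.fill_diagonal(v, 1)
        self.values = v


def binarize(mi: MiMatrix, t_mi: float) -> BinarySimilarity:
    """Threshold an MI matrix: entries >= ``t_mi`` become 1, others 0."""
    if t_mi < 0:
        raise ValueError("t_mi must be non-negative")
    sim = (mi.values >= t_mi).astype(np.int8)
    np.fill_diagonal(sim, 1)
    return BinarySimilarity(sim, list(mi.variable_ids))


def cast(sim: BinarySimilarity, t_cast: float) -> list[list]:
    """Partition variables into disjoint clusters by the CAST heuristic.

    Deterministic policy: each new cluster opens on the unassigned variable
    of maximal degree among unassigned variables (ties → lowest index); each
    pass adds the single eligible non-member of highest affinity (ties →
    lowest index), then repeatedly removes the single ineligible member of
    lowest affinity (ties → highest index).  A non-member x is eligible when
    a(x) ≥ t_cast·|C|; a member is retained while its affinity to the other
    members is ≥ t_cast·(|C|−1).  Affinities count similarity-1 links to
    other members only.  Variables with no similarity-1 neighbour are emitted
    as singletons immediately.
    """
    if not 0.0 < t_cast <= 1.0:
        raise ValueError(f"t_cast must lie in (0, 1], got {t_cast}")
    m = sim.values.shape[0]
    if m == 0:
        raise ValueError("empty variable set")
    adj = sim.values.astype(np.int64).copy()
    np.fill_diagonal(adj, 0)

    unassigned = list(range(m))
    clusters: list[list[int]] = []
    max_passes = 2 * m * m + 10

    while unassigned:
        sub = adj[np.ix_(unassigned, unassigned)]
        degrees = sub.sum(axis=1)
        isolated = [u for u, d in zip(unassigned, degrees) if d == 0]
        if isolated:
            for u in isolated:
                clusters.append([u])
            unassigned = [u for u in unassigned if u not in set(isolated)]
            continue
        # seed: maximal degree among unassigned, ties -> lowest index
        seed = unassigned[int(np.argmax(degrees))]
        open_c = [seed]
        pool = [u for u in unassigned if u != seed]

        for _ in range(max_passes):
            changed = False
            # add phase: single highest-affinity eligible non-member
            if pool:
                aff = adj[np.ix_(pool, open_c)].sum(axis=1)
                need = t_cast * len(open_c)
                best, best_aff = None, -1
                for u, a in zip(pool, aff):
                    if a >= need and a > best_aff:  # ties -> lowest index (first)
                        best, best_aff = u, a
                if best is not None:
                    open_c.append(best)
                    pool.remove(best)
                    changed = True
            # remove phase: repeatedly drop lowest-affinity ineligible member
            while len(open_c) > 1:
                aff = adj[np.ix_(open_c, open_c)].sum(axis=1)
                need = t_cast * (len(open_c) - 1)
                worst, worst_aff = None, None
                for u, a in zip(open_c, aff):
                    if a < need and (worst_aff is None or a < worst_aff
                                     or (a == worst_aff and u > worst)):
                        worst, worst_aff = u, a
                if worst is None:
                    break
                open_c.remove(worst)
                pool.append(worst)
                pool.sort()  # keep ascending order so add-ties go to lowest index
                changed = True
            if not changed:
                break
        clusters.append(sorted(open_c))
        closed = set(open_c)
        unassigned = [u for u in unassigned if u not in closed]

    ids = sim.variable_ids
    return [[ids[i] for i in c] for c in clusters]


def check_partition(clusters: list[list], variable_ids: list) -> bool:
    """True iff ``clusters`` is a disjoint cover of ``variable_ids``."""
    flat = [v for c in clusters for v in c]
    return len(flat) == len(set(flat)) and set(flat) == set(variable_ids)
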