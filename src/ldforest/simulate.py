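"""Synthetic SNP data: block-LD haplotype/genotype simulation and exact
sampling from a fully parameterized forest model.

The block-LD generator emulates the haplotype-block structure of real
panels at desk scale: each block carries a small pool of ancestral
haplotypes; every sampled haplotype copies one pool member and then flips
each allele independently with probability (1 − fidelity)/2, so the
realized within-block r² increases monotonically with fidelity while blocks
stay mutually independent.  It is a simple surrogate for coalescent-based
simulators — no recombination maps or population substructure.

The forest sampler draws exact ancestral samples (roots from their priors,
children from their CPTs) from any parameterized forest, returning the true
latent values for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Coding, SnpMatrix
from .forest import Forest


@dataclass
class GeneratorSpec:
    """Block-LD generator settings.

    blocks: list of (n_snps, n_ancestral_haplotypes, fidelity) triples;
    fidelity in [0, 1] is the per-allele copy probability complement of the
    flip noise: alleles are flipped with probability (1 − fidelity)/2.
    """

    n_individuals: int
    blocks: list[tuple[int, int, float]]
    coding: Coding = Coding.haplotype_01
    seed: int = 0

    def __post_init__(self) -> None:
        self.coding = Coding(self.coding)
        for size, n_anc, fid in self.blocks:
            if size < 1 or n_anc < 1:
                raise ValueError("block sizes and pool sizes must be >= 1")
            if not 0.0 <= fid <= 1.0:
                raise ValueError("fidelity must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return sum(size for size, _, _ in self.blocks)

    def block_labels(self) -> np.ndarray:
        """Block index of each SNP column."""
        return np.concatenate([
            np.full(size, k, dtype=np.int64)
            for k, (size, _, _) in enumerate(self.blocks)])


def _ancestral_pool(rng: np.random.Generator, size: int,
                    n_anc: int) -> np.ndarray:
    """Distinct random haplotypes in {0,1}^size (duplicates rejected)."""
    n_anc = min(n_anc, 2 ** min(size, 62))
    pool: list[tuple] = []
    seen = set()
    while len(pool) < n_anc:
        h = tuple(rng.integers(0, 2, size=size))
        if h not in seen:
            seen.add(h)
            pool.append(h)
    return np.array(pool, dtype=np.int64)


def generate_block_ld(spec: GeneratorSpec) -> SnpMatrix:
    """Sample a block-LD SNP matrix according to ``spec``.

    Haplotype coding yields ``n_individuals`` rows in {0,1} (one row per
    haplotype); genotype coding draws two haplotypes per individual and sums
    them into {0,1,2} dosages.
    """
    rng = np.random.default_rng(spec.seed)
    n_haps = (2 * spec.n_individuals
              if spec.coding is Coding.genotype_012 else spec.n_individuals)
    cols = []
    for size, n_anc, fidelity in spec.blocks:
        pool = _ancestral_pool(rng, size, n_anc)
        picks = rng.integers(0, len(pool), size=n_haps)
        haps = pool[picks]
        flips = rng.random((n_haps, size)) < (1.0 - fidelity) / 2.0
        cols.append(np.where(flips, 1 - haps, haps))
    haps = np.concatenate(cols, axis=1)
    if spec.coding is Coding.genotype_012:
        values = haps[0::2] + haps[1::2]
    else:
        values = haps
    return SnpMatrix(values, spec.coding)


def haplotypes_to_genotypes(haps: SnpMatrix) -> SnpMatrix:
    """Sum haplotype rows 2i and 2i+1 into genotype dosages."""
    if haps.coding is not Coding.haplotype_01:
        raise ValueError("input must be haplotype-coded")
    if haps.n % 2:
        raise ValueError("odd number of haplotype rows")
    values = haps.values[0::2] + haps.values[1::2]
    return SnpMatrix(values, Coding.genotype_012,
                     marker_names=list(haps.marker_names),
                     positions=haps.positions, chromosome=haps.chromosome)


def sample_fhlcm(forest: Forest, n: int, seed=None,
                 coding: Coding | None = None) -> tuple[SnpMatrix, pd.DataFrame]:
    """Exact ancestral sampling of ``n`` individuals from a forest model.

    Roots are drawn from their priors, every other node from its CPT given
    the sampled parent value.  Returns the observed matrix and the true
    latent values (for recovery experiments).
    """
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    order = sorted(forest.nodes, key=lambda nid: -forest.nodes[nid].layer)
    for nid in order:
        if nid not in forest.parent:
            prior = forest.priors[nid]
            if abs(prior.sum() - 1) > 1e-9 or (prior < 0).any():
                raise ValueError(f"invalid prior for {nid}")
            values[nid] = _draw_categorical(rng, np.tile(prior, (n, 1)))
        else:
            cpt = forest.cpts[nid]  # (child_card, parent_card)
            if np.abs(cpt.sum(axis=0) - 1).max() > 1e-9 or (cpt < 0).any():
                raise ValueError(f"invalid CPT for {nid}")
            parent_vals = values[forest.parent[nid]]
            values[nid] = _draw_categorical(rng, cpt.T[parent_vals])
    obs = np.column_stack([values[nid] for nid in forest.observed_ids])
    if coding is None:
        max_card = max(forest.nodes[nid].cardinality
                       for nid in forest.observed_ids)
        coding = Coding.genotype_012 if max_card == 3 else Coding.haplotype_01
    matrix = SnpMatrix(obs, coding, marker_names=list(forest.observed_ids))
    latents = pd.DataFrame({nid: values[nid] for nid in forest.latent_ids})
    return matrix, latents


def _draw_categorical(rng: np.random.Generator,
                      probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw from an (n, K) probability matrix."""
    u = rng.random(probs.shape[0])
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.int64)


def random_block_spec(n_individuals: int, total_snps: int,
                      block_size_range: tuple[int, int] = (10, 20),
                      n_ancestral: int = 4, fidelity: float = 0.95,
                      coding: Coding = Coding.genotype_012,
                      seed: int = 0) -> GeneratorSpec:
    """Spec with consecutive blocks of random size until ``total_snps`` is
    reached (the last block may overshoot by less than one block)."""
    rng = np.random.default_rng(seed)
    lo, hi = block_size_range
    blocks: list[tuple[int, int, float]] = []
    p = 0
    while p < total_snps:
        size = int(rng.integers(lo, hi + 1))
        blocks.append((size, n_ancestral, fidelity))
        p += size
    return GeneratorSpec(n_individuals, blocks, coding=coding, seed=seed)


# -- ready-made generating forests for recovery experiments -----------------

def symmetric_cpt(card_child: int, card_parent: int,
                  fidelity: float) -> np.ndarray:
    """CPT where the child copies the parent state with prob ``fidelity``.

    Off-target mass is spread uniformly; for unequal cardinalities the
    parent state is taken modulo the child cardinality.
    """
    cpt = np.full((card_child, card_parent),
                  (1.0 - fidelity) / max(card_child - 1, 1))
    for h in range(card_parent):
        cpt[h % card_child, h] = fidelity
    return cpt / cpt.sum(axis=0, keepdims=True)


def make_layered_forest(n_groups: int = 8, leaves_per_group: int = 5,
                        groups_per_parent: int = 2,
                        leaf_fidelity: float = 0.95,
                        edge_fidelities: tuple[float, ...] = (0.925,),
                        n_noise: int = 20,
                        cardinality: int = 2,
                        coding: Coding = Coding.haplotype_01) -> Forest:
    """A known layered forest for simulation and recovery studies.

    ``n_groups`` layer-1 latent variables each parent ``leaves_per_group``
    observed SNPs through copy-with-noise CPTs of strength
    ``leaf_fidelity``.  Each entry of ``edge_fidelities`` stacks one more
    latent layer: consecutive runs of ``groups_per_parent`` latent variables
    of the previous layer share a new parent whose CPTs copy the parent
    state with the given fidelity.  ``n_noise`` additional SNPs are isolated
    uniform roots — they emulate the unclustered markers of real panels and
    keep dependent pairs a minority of the MI matrix, which is the regime
    the default 0.95 MI quantile threshold expects.
    """
    forest = Forest()
    leaf_card = coding.cardinality
    snp = 0
    group_children: list[list[str]] = []
    for _ in range(n_groups):
        ids = []
        for _ in range(leaves_per_group):
            snp += 1
            nid = f"SNP{snp}"
            forest.add_observed(nid, leaf_card)
            ids.append(nid)
        group_children.append(ids)
    for _ in range(n_noise):
        snp += 1
        forest.add_observed(f"SNP{snp}", leaf_card,
                            prior=np.ones(leaf_card) / leaf_card)
    uniform = np.ones(cardinality) / cardinality
    leaf_cpt = symmetric_cpt(leaf_card, cardinality, leaf_fidelity)
    current = []
    for g, ids in enumerate(group_children):
        name = f"H1_{g + 1}"
        forest.add_latent(name, cardinality, ids, uniform,
                          [leaf_cpt.copy() for _ in ids],
                          np.zeros(0, dtype=np.int64))
        current.append(name)
    for level, fidelity in enumerate(edge_fidelities, start=2):
        edge_cpt = symmetric_cpt(cardinality, cardinality, fidelity)
        nxt = []
        for k in range(0, len(current) - groups_per_parent + 1,
                       groups_per_parent):
            block = current[k:k + groups_per_parent]
            if len(block) < 2:
                break
            name = f"H{level}_{k // groups_per_parent + 1}"
            forest.add_latent(name, cardinality, block, uniform,
                              [edge_cpt.copy() for _ in block],
                              np.zeros(0, dtype=np.int64))
            nxt.append(name)
        current = nxt
        if len(current) < groups_per_parent:
            break
    forest.imputed = None  # generating model: no imputed data
    return forest
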