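# Methods

## Model

An FHLCM is a directed forest over discrete variables. Layer 0 holds the
observed SNPs — genotype dosages in {0, 1, 2} or haplotype alleles in {0, 1};
phased data are treated as two haplotype rows per individual. Every internal
node is a latent variable (LV) with a finite number of states; every node has
at most one parent, and a node's layer is 1 + the maximum layer of its
children. Roots carry prior distributions and non-roots conditional
probability tables (CPTs) given their parent, so the joint factorizes as
∏ P(node | parent). Windows are independent by construction — no edge crosses
a window boundary — so the full joint is the product of per-window factors.

The model assumes (i) within a cluster, children are conditionally independent
given their latent parent (the latent class assumption), and (ii) dependence
between markers is local enough to be captured within a window of `s`
consecutive markers. Long-range LD beyond the window span is invisible to the
construction.

## Parameters

| name | default | meaning |
|---|---|---|
| `window_size` (s) | 100 | markers per window (index-based, not bp) |
| `t` | 0.3 | validation floor on criterion C, in [0, 1] |
| `a`, `b` | 0.2, 2 | affine cardinality rule min(⌊a·size+b⌋, card_max) |
| `card_max` | 20 | latent-cardinality cap (model-complexity guard) |
| `t_cast` | 0.95 | CAST affinity threshold, in (0, 1] |
| `mi_quantile` (q) | 0.95 | MI-matrix quantile defining the binarization threshold t_MI |
| `t_mi_policy` | "step" | recompute t_MI each agglomerative step, or hold the layer-0 value per window ("window") |
| `imputation_mode` | "map" | posterior mode; "sample" draws from the exact posterior |
| `n_restarts`, `max_iter`, `tol` | 3, 500, 1e-6 | EM restarts, iteration cap, relative log-likelihood tolerance |
| `seed` | 0 | master seed; per-window/step/cluster sub-seeds are spawned deterministically |

The affine cardinality rule is floored at 2 (a latent variable needs at least
two states). The exponential alternative — the product of child cardinalities
divided by their maximum — is exposed as
`regularization_cardinality` for reference; for ten ternary children it
already yields 3⁹ = 19683 states, which is why the affine rule is used in the
construction.

## Information measures

All entropies and mutual informations are plug-in (maximum-likelihood)
estimates in bits with 0·log 0 := 0; no bias correction is applied. Scaled MI
is MI / min(H(x), H(y)), defined as 0 when either variable is constant — a
variable carrying no information is never counted as captured, which blocks
vacuous LVs over constant columns. Quantiles of the MI matrix are
nearest-rank over the strictly-upper triangle (the diagonal would inflate the
threshold). r² is the squared Pearson correlation of the numeric codes:
allelic r² on haplotypes, composite r² on genotype dosages (no two-locus
haplotype-frequency EM is attempted).

## CAST determinism

CAST is specified up to several free choices; this implementation fixes them
for reproducibility: a new cluster opens on the unassigned variable of maximal
degree among unassigned variables (ties → lowest index); each pass first adds
the single eligible non-member of highest affinity (ties → lowest index), then
repeatedly removes the single ineligible member of lowest affinity (ties →
highest index) until stable. Affinity counts similarity-1 links to other
members; a non-member x is eligible when a(x) ≥ t_cast·|C| and a member is
retained while a(x) ≥ t_cast·(|C|−1) — the member bar is set against the
number of *other* members so that a complete graph forms a single cluster even
at t_cast = 1. Variables with no similarity-1 neighbour are emitted as
singletons immediately. A pass cap of 2·m² guards against add/remove cycles on
adversarial graphs.

## EM and imputation

Each cluster is fitted as a one-root latent class model. Restarts draw the
prior and each CPT column from a symmetric Dirichlet(1); the E-step is
computed in log space; responsibilities receive 1e-9 smoothing before M-step
normalization to avoid zero-probability lock-in; convergence is declared when
the relative log-likelihood change falls below `tol`. The best restart by
final log-likelihood wins, and its log-likelihood trace (non-decreasing up to
1e-8) is kept as a diagnostic. MAP imputation breaks posterior ties toward the
lowest state index; sampled imputation uses the exact per-individual
posterior.

Criterion C is computed from the *imputed* latent column, not from the
analytic posterior MI. This matches the pipeline semantics: the imputed column
is exactly what becomes the next layer's data, so validation measures the
information actually propagated upward. MAP imputation is the default; it
loses the probabilistic relation between child and parent but is roughly twice
as fast as sampling and deterministic.

## The t_MI policy and the pair-saturation plateau

A two-child cluster with a binary-or-larger latent variable can always be
fitted to the saturated joint, in which case the latent column reproduces one
child and C = (1 + ε)/2 ≈ 0.5 regardless of whether the children are actually
dependent. Best-of-restarts EM finds this solution for the majority of seeds
even on independent children. Consequences worth knowing:

- at the default t = 0.3, pair clusters proposed on noise-level MI can
  validate; on LD-dense inputs this is rare at early steps (the 0.95-quantile
  threshold only proposes strongly dependent pairs) but becomes possible late
  in the agglomeration, when the working-set MI matrix is mostly noise. These
  late spurious merges add high-layer nodes with near-zero edge information;
  they lower the root count but are visibly uninformative in
  `layer_statistics` and in the per-edge scaled MI.
- setting t > 0.5 puts the validation floor above the saturation plateau and
  removes the effect entirely; t = 0.6 is the setting used for the simulated
  LD-degree sweeps, and several structural unit tests run there because stop
  conditions are then exact.
- `t_mi_policy="window"` (hold t_MI at the layer-0 quantile for the whole
  window) prevents the proposal of noise pairs after the first step and makes
  the all-singletons stop condition reachable, at the cost of a markedly lower
  dimensionality reduction on block-LD data (the fixed threshold lands inside
  the within-block MI band and strands block fragments). The per-step default
  reproduces the headline reduction behaviour; the window policy is kept for
  structure-first analyses.

## Synthetic data

`generate_block_ld` emulates haplotype-block structure at desk scale: each
block holds a small pool of distinct ancestral haplotypes; each sampled
haplotype copies one pool member and flips every allele independently with
probability (1 − fidelity)/2; genotypes sum two sampled haplotypes. Blocks are
mutually independent. Realized within-block r² increases monotonically with
fidelity, which is the only property the LD-degree sweeps rely on. The
generator is *not* a coalescent simulator: no recombination maps, no allele
frequency spectrum, no population substructure, no physical positions — so
passing recovery tests demonstrates correctness of the construction on
block-structured dependence, not performance on real cohort data.

`sample_fhlcm` draws exact ancestral samples (roots from priors, children from
CPTs) from any parameterized forest and returns the true latent values.
`make_layered_forest` builds the recovery benchmark: eight 5-SNP clusters with
copy-with-noise CPTs (leaf fidelity 0.95), optionally stacked layer-2/layer-3
parents (fidelities 0.925 / 0.975), plus 20 isolated noise SNPs. The noise
SNPs keep dependent pairs a minority of the MI matrix — the regime the
0.95-quantile threshold is designed for, and the analogue of the unclustered
markers seen in real panels; the stacked fidelities are chosen so each layer's
between-cluster dependence clears the t = 0.3 validation floor with margin
under the binary-symmetric-channel MI budget.

## Problem sizes used in the shipped experiments

The packaged tests and the reproduction script use: 2000 individuals ×
~1000 SNPs (blocks of 10–20, fidelity 0.95) for the dimensionality-reduction
experiment; 2000 × 60 for the cluster-recovery and MRCA/r² experiments
(10 and 5 seeds respectively); 800 × 60 over 10 seeds for the fidelity sweep.
These sizes give stable medians while keeping a full run of the suite and the
script in the minutes range on a single CPU.

## Degenerate inputs and numerical choices

Missing calls (−1) are imputed to the per-marker mode (ties toward the smaller
code) before any modeling, with a logged count. All-constant cluster data fit
to a degenerate but valid model with a warning. Empty vectors, constant
columns passed to r², unknown serialization dialects, and cardinalities below
2 raise `ValueError`. Forest serialization stores CPT entries as JSON floats
(exact repr round-trip); GraphML carries them as JSON-encoded node attributes.

## Limitations

- Windows are index-based and non-overlapping; dependence across window
  boundaries is never modeled.
- CAST is a heuristic: on ambiguous (non-clique) similarity graphs the
  partition depends on the documented tie-break policy.
- The validation criterion saturates at 0.5 for two-child clusters (above).
- Genotype r² is the composite approximation; D′ and phased-EM r² are not
  implemented.
- Trio phasing, PLINK formats and multi-allelic sites (beyond skipping) are
  out of scope.
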