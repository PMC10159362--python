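# Methods

## Model

A multilayer network here is `G = (V, L, E)`: one node set of size `n`
replicated across `L` layers, undirected nonnegative weighted edges both
within a layer and between arbitrary node pairs in different layers, no
self-edges. The supra-adjacency matrix `M` (size `N = n·L`, supra-index of
node `i` in layer `α` is `α·n + i`) splits uniquely into the block-diagonal
intra-layer part `A` and the off-block inter-layer part `C`. Heterogeneous
networks (different node sets per layer) are represented by taking the
union of node identifiers in every layer; genes absent from a tissue simply
have zero rows in that layer.

## Normalization and operator orientation

All fixed-point solvers run on the *jointly* normalized decomposition: each
row of `M = A + C` with positive sum is divided by that sum, the same
factor applied to the `A`- and `C`-parts of the row so the block split is
preserved. Rows of isolated supra-nodes stay zero; this is safe because
each solver's linear operator then has spectral radius at most `p < 1`, so
the teleportation term alone guarantees a unique fixed point.

The solvers apply the normalized matrices in the *transition* (PageRank)
orientation — the transpose of the row-normalized matrix, which for an
undirected network is its column-normalized counterpart. A node's score
therefore accumulates incoming random-walk mass, each neighbor
contributing in proportion to edge weight over that neighbor's total
degree. This choice is forced, not stylistic: a row-stochastic matrix fixes
the all-ones vector, so applying the row-normalized `M` un-transposed would
make every uniform-forcing measure (versatility, and local + global
jointly) *exactly* uniform and useless for ranking. All convergence and
decomposability results are algebraic identities in `A` and `C` and hold
unchanged under transposition.

## The centrality hierarchy

With restart parameter `p` and writing `1_[i]` for the indicator of layer
`i` and `1_i^k` for the indicator of query set `k` inside layer `i`:

* local: `l = pAl + (1−p)/n·1`
* layer-local: `l_i = pA^[i] l_i + (1−p)/n·1_[i]`, where `A^[i]` zeroes
  every column block of `A` except layer `i`'s (for block-diagonal `A` this
  leaves exactly the layer's own adjacency block, so `l_i` vanishes outside
  layer `i`)
* global: `g = p[(A+C)g + Cl] + (1−p)/N·1`
* layer-specific: `g_i = p[(A+C)g_i + Cl_i] + (1−p)/N·1_[i]`
* local-set: `l_i^k = pA^[i] l_i^k + (1−p)/n·1_i^k`
* query-set: `g_i^k = p[(A+C)g_i^k + Cl_i^k] + (1−p)/N·1_i^k`
* versatility: `x = pMx + (1−p)/N·1` (PageRank on the full supra-adjacency)

Exact identities (enforced at 1e-8 in the test suite on randomized
instances): `Σ_i l_i = l`; `Σ_i g_i = g`; for any partition of layer `i`,
`Σ_k l_i^k = l_i` and `Σ_k g_i^k = g_i`; and `l + g = (L+1)·x`, so local
plus global equals versatility after unit-sum normalization. Reported
scores are raw fixed points; unit-sum normalization is applied only for
cross-measure comparisons, since all of these vectors are scale-agnostic.

Baselines: intra-/inter-layer degree are row sums of the *unnormalized*
`A` and `C` (the inter-layer degree optionally restricted to the columns
of a query set, which is also the published protocol for benchmarking
degree and versatility against a known query set; with `−ln p`-value edge
weights supplied by the caller, the restricted inter-layer degree is the
S_sec score of earlier endocrine-interaction work). RWR-H column-normalizes
`A` and `C` *separately*, mixes them as `(1−λ)Ã + λC̃` (λ = 0.5 by
default), and restarts at a seed set with probability `1−p`; zero columns
are left zero, so a walker restarting at a node with no edges of one type
loses that mixture share (lazy absorption) and scores sum to at most one.

## Numerics

Fixed points are computed by simple iteration `v ← p·T v + b` starting at
`b` (the exact `p = 0` solution), stopping when the L∞ change is below the
tolerance (default 1e-10, cap 1000 iterations). Convergence is geometric at
rate `p`, so the default cap is ample for `p ≤ 0.95`; runs at `p` near one
need a larger `max_iter` (both knobs are exposed). Reaching agreement with
a direct linear solve to 1e-8 *relative* error requires a tolerance below
the default; the verification suites use 1e-12. Iteration counts shrink as
`p` decreases; per-measure counts can wobble by a step because the forcing
amplitude scales with `1−p` under an absolute stopping rule.

Default `p = 0.85`, the classic PageRank damping value; it is a required,
logged configuration knob rather than a constant. Rankings sort scores
descending with ties broken by node identifier (stable and reproducible;
ties are common only in degenerate networks).

## Synthetic benchmark

The generator emulates hormone signaling between two tissues. Defaults are
the benchmark's study conditions: two layers of 500 nodes; a base
Erdős–Rényi pass over *all* supra-node pairs at probability 0.05 with
weight one; communities of 50 nodes; extra ER edges at the *connection
strength* (swept 0.05…1 in the published protocol) within the query set
(layer 2), within source set 1 and source set 2 (layer 1), between the two
source sets, and across layers between source set 1 and the query set; a
pair hit by both passes gets weight two. Model 2 adds a second layer-2
community tied to the query set. Three decoy communities (in layer 1, the
source layer, by default — configurable) get the same treatment within and
between all pairs of them at `background_strength` (defaulting to the main
strength, matching the protocol of varying them together). By construction
a decoy node carries about the same planted weight (49 + 2·50 pair slots)
as a source-set-1 node (49 + 50 + 50), so degree alone cannot separate
signal from decoys — the separation must come from query awareness.
Community membership uses contiguous index blocks: reproducible, and
exchangeable with random subsets because the base graph is exchangeable.

Ground truth mixes the source sets: `floor(x·50)` nodes drawn from source
set 2 (reachable from the query set only through source set 1) and the rest
from source set 1, sampled without replacement under a seed. `x = 0` is the
pure direct-connection regime; `x = 1` the pure two-hop regime.

Scaled-down study sizes used by the acceptance script and tests: 200 nodes
per layer, community size 30, recall evaluated at k = 60 over the 200
layer-1 nodes, 10 seeds — large enough that the base-graph noise does not
swamp the planted structure, small enough to run in seconds.

## Coexpression network construction

Within-layer edge weights are `|Spearman ρ|` over all of a tissue's
samples; cross-layer weights are `|ρ|` over the subjects shared by the two
tissues (sample identifiers are subject-level; at least three shared
subjects are required per pair). The graph is kept complete — no
correlation threshold is applied by default, with an optional prune
threshold exposed — because the centrality measures consume weights
directly. Correlations with a constant profile are undefined and stored as
zero. The per-tissue variance filter keeps the top-k genes by sample
variance (ties by identifier) and layers are built over the union.
Protein-interaction augmentation adds one weight unit to an annotated pair
in *every* layer, on the view that a physical interaction is evidence in
each tissue where both genes are present. Covariate adjustment replaces
each gene's profile with its least-squares residual against an
intercept-plus-covariates design (categoricals one-hot encoded, first level
dropped; rank-deficient designs rejected naming the collinear columns),
with the gene's mean restored.

The expression fixture generator plants one module whose genes load on a
shared per-sample latent factor with loading √ρ in every tissue, giving
pairwise correlation ρ within and across tissues; all other genes are
independent Gaussian noise, and all tissues share subjects. It emulates a
tight co-regulated cross-tissue module on an empty background — it has no
library-size, batch, outlier or heavy-tail structure, so pipeline tests
against it demonstrate correctness of the machinery, not robustness to
real RNA-seq artifacts.

## Evaluation

`recall(k) = |top-k ∩ truth| / |truth|` over the full ranked universe; the
normalized area is the mean recall over all `k` divided by the mean for the
ideal ranking (truth first), so the ideal scores exactly 1 and a uniformly
random ranking about `(n+1)/(2n)` of the ideal mean — ≈ 0.51 for small
truth sets. For query-driven gene ranking the evaluation universe is the
target layer's nodes (excluding the query set when it lives in the same
layer). Matched null sets stratify genes at the 33rd/66th variance
percentiles (closed intervals, boundary genes to the lower stratum) and
draw per-stratum counts matching the target set. Literature co-occurrence
support is the observed/expected ratio `(joint/(H·G))·corpus` with a corpus
constant of 27,000,000 articles; the printed source formula's typography is
ambiguous and this independence-ratio reading is the one consistent with
the "support ≥ 1" evidence threshold. Delta ranks are
`rank_in_first − rank_in_second` over a shared universe.

## Known limitations

* Dense `numpy` matrices throughout: simple and exact at the sizes used
  here (N up to a few thousand); genome-scale networks (10k genes × several
  layers) would need a sparse or blocked backend.
* Undirected networks only; no temporal layers; no automatic multiplex
  coupling edges.
* The benchmark's conclusions transfer to real coexpression networks only
  qualitatively: real edge weights are noisy correlations, not planted ER
  communities.
* RWR-H's lazy absorption at structurally empty columns means its scores
  are comparable across nodes within one network but not across networks
  with different sparsity patterns.
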