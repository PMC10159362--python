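# multicens

Hierarchical centrality measures for weighted multilayer networks, built for
finding molecular mediators of tissue–tissue communication.

## The problem

Inter-organ signaling (hormones, brain-region crosstalk) is carried by genes
whose influence spans tissues, often through multi-hop paths: a pancreatic
gene may affect insulin-responsive genes in skeletal muscle only via
intermediary genes in either tissue. Single-layer centralities cannot
separate a gene's within-tissue importance from its cross-tissue influence,
and degree-based cross-tissue scores see only direct edges.

`multicens` models a multi-tissue system as an undirected weighted
multilayer network: the same `n` genes replicated across `L` layers
(tissues), with arbitrary within- and across-layer edges collected in a
supra-adjacency matrix `M = A + C` of size `N = n·L`, where `A` holds the
block-diagonal intra-layer weights and `C` the inter-layer weights.

## The measures

With `M` jointly degree-normalized and applied as a random-walk transition
operator (PageRank orientation), and restart parameter `p ∈ [0, 1)`:

| measure | fixed point | captures |
|---|---|---|
| local `l` | `l = pAl + (1−p)/n·1` | within-layer influence |
| global `g` | `g = p[(A+C)g + Cl] + (1−p)/N·1` | cross-layer-aware influence |
| layer-specific `g_i` | `g_i = p[(A+C)g_i + Cl_i] + (1−p)/N·1_[i]` | influence on one target layer |
| query-set `g_i^k` | `g_i^k = p[(A+C)g_i^k + Cl_i^k] + (1−p)/N·1_i^k` | influence on a gene set in that layer |

The hierarchy decomposes exactly: layer-local vectors sum to `l`,
layer-specific vectors sum to `g`, query-set vectors over a partition of a
layer sum to its layer-specific vector, and `l + g = (L+1)·x` where `x` is
PageRank versatility on the full supra-adjacency. All solvers are plain
fixed-point iterations with guaranteed geometric convergence for `p < 1`,
cross-checked in the test suite against dense linear solves.

**Query-set centrality (QC)** is the ranking measure: seed it with, say, the
insulin-responsive genes in muscle and it scores every gene in every tissue
by its multi-hop influence on that set — the pancreas genes at the top are
candidate mediators. Baselines included for comparison: intra-/inter-layer
degree, PageRank versatility, and RWR-H (random walk with restart with an
inter-layer jump probability λ, default 0.5).

The package also ships: a two-layer synthetic benchmark generator with
planted source/query communities and degree-matched decoy communities;
multi-tissue coexpression network construction (|Spearman ρ| edges,
per-tissue samples within layers, shared subjects across layers, top-k
variance gene filter, optional +1 protein-interaction augmentation, linear
covariate residualization); and ranking evaluation (recall-at-k, normalized
AUC, variance-stratified matched random gene sets, delta ranks,
literature co-occurrence support, embedding cosine similarity).

## Worked example

Generate a benchmark network (model 2, 200 genes/layer, 30-gene
communities, connection strength 0.6, half the ground truth two hops away
from the query set), rank layer-1 genes by query-set centrality, and score
the ranking:

```sh
multicens synth --model 2 --n 200 --community-size 30 --strength 0.6 \
    --x 0.5 --seed 7 -o net.tsv --truth truth.json
printf 'layer1\nlayer2\n' > layers.txt
python -c "import json; t=json.load(open('truth.json')); \
    open('query.txt','w').write('\n'.join(t['query_set'])); \
    open('gt.txt','w').write('\n'.join(t['ground_truth']))"
multicens centrality --measure query-set --network net.tsv \
    --layers layers.txt --target-layer layer2 --query query.txt \
    --p 0.85 -o scores.tsv
multicens evaluate --scores scores.tsv --truth gt.txt --layer layer1 \
    --recall-k 60 -o eval.json
```

Output:

```
{"n_candidates": 200, "truth_size": 30,
 "recall_at_k": {"k": 60, "recall": 0.6666666666666666},
 "auc": 0.8251572327044024}
```

20 of the 30 planted ground-truth genes appear in the top 60 of the 200
ranked layer-1 genes, and the recall-at-k curve covers 83% of the area an
ideal ranking would (0.5 is chance). At this moderate strength the directly
connected half of the truth is recovered almost entirely; the two-hop half
is harder, which is exactly the regime where query-set centrality separates
from degree-based baselines (see the benchmark subcommand for the full
strength sweep).

Other subcommands: `build-network` (expression matrices → multilayer
coexpression network), `baseline`, `benchmark` (full strength/x/seed
sweep as a TSV table), `support`, `fixture`. All accept `--help`.

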