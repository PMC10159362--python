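"""Ranking evaluation and literature-support scoring.

Recall-at-k curves and their normalized area summarize how early a ranking
recovers a ground-truth node set; variance-stratified random gene sets give
a matched null for centrality scores; delta ranks compare two rankings of
the same universe; the co-occurrence support score and embedding cosine
similarity quantify literature evidence for predicted gene-hormone (or
gene-disease) links.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

PUBMED_CORPUS_SIZE = 27_000_000


@dataclass
class RankingEvaluation:
    """Recall-at-k curve over the whole ranked universe plus its area."""

    ks: np.ndarray
    recall: np.ndarray
    n_candidates: int
    truth_size: int

    @property
    def auc(self) -> float:
        return auc_recall(self)

    def recall_at(self, k: int) -> float:
        if not (1 <= k <= self.n_candidates):
            raise ValueError(f"k must lie in 1..{self.n_candidates}; got {k}")
        return float(self.recall[k - 1])


def recall_at_k(ranking: Sequence[str], truth: set[str]) -> RankingEvaluation:
    """recall(k) = |top-k intersect truth| / |truth| for k = 1..len(ranking)."""
    truth = {str(t) for t in truth}
    if not truth:
        raise ValueError("ground-truth set must be nonempty")
    universe = [str(r) for r in ranking]
    missing = truth - set(universe)
    if missing:
        raise ValueError(
            f"ground-truth nodes outside the ranked universe: {sorted(missing)[:5]}"
        )
    hits = np.fromiter((r in truth for r in universe), dtype=float, count=len(universe))
    recall = np.cumsum(hits) / len(truth)
    return RankingEvaluation(
        ks=np.arange(1, len(universe) + 1),
        recall=recall,
        n_candidates=len(universe),
        truth_size=len(truth),
    )


def auc_recall(ev: RankingEvaluation) -> float:
    """Mean recall over all k, normalized so an ideal ranking scores one.

    The ideal ranking places the whole truth set first; a uniformly random
    ranking has expected normalized area just above one half for small
    truth sets.
    """
    mean_recall = float(ev.recall.mean())
    n, t = ev.n_candidates, ev.truth_size
    # ideal curve: k/t for k <= t, then 1
    ideal_mean = (np.minimum(np.arange(1, n + 1), t) / t).mean()
    return mean_recall / ideal_mean


def delta_ranks(r1: Sequence[str], r2: Sequence[str]) -> dict[str, int]:
    """Per-node rank difference rank_in_r1 - rank_in_r2 (ranks are 1-based).

    A positive delta means the node ranks better (earlier) in ``r2``.
    """
    u1, u2 = list(map(str, r1)), list(map(str, r2))
    if set(u1) != set(u2) or len(u1) != len(set(u1)) or len(u2) != len(set(u2)):
        raise ValueError("rankings must be permutations of the same universe")
    pos2 = {node: i + 1 for i, node in enumerate(u2)}
    return {node: (i + 1) - pos2[node] for i, node in enumerate(u1)}


def stratified_random_sets(
    variances: dict[str, float],
    target: set[str],
    n_draws: int,
    seed: int,
) -> list[set[str]]:
    """Random gene sets matching the target's variance-stratum composition.

    Genes are split into low/medium/high variance strata at the 33rd and
    66th percentiles (closed intervals; boundary genes go to the lower
    stratum).  Each draw samples, without replacement within the draw, the
    same number of genes per stratum as the target set contains.
    """
    genes = sorted(variances)
    target = {str(t) for t in target}
    missing = target - set(genes)
    if missing:
        raise ValueError(f"target genes without variances: {sorted(missing)[:5]}")
    values = np.array([variances[g] for g in genes])
    lo, hi = np.percentile(values, [33, 66])
    stratum_of = {
        g: ("low" if v <= lo else "medium" if v <= hi else "high")
        for g, v in zip(genes, values)
    }
    strata = {name: [g for g in genes if stratum_of[g] == name]
              for name in ("low", "medium", "high")}
    need = {name: sum(stratum_of[t] == name for t in target) for name in strata}
    for name, count in need.items():
        if count > len(strata[name]):
            raise ValueError(
                f"stratum {name!r} has {len(strata[name])} genes but the "
                f"target needs {count}"
            )
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        picked: set[str] = set()
        for name, count in need.items():
            if count:
                picked |= set(rng.choice(strata[name], size=count, replace=False))
        draws.append(picked)
    return draws


def cooccurrence_support(
    h_count: int,
    g_count: int,
    joint_count: int,
    corpus_size: int = PUBMED_CORPUS_SIZE,
) -> float:
    """Observed/expected co-mention ratio of two terms in a literature corpus.

    support = (joint / (h * g)) * corpus_size: the number of articles
    mentioning both terms relative to the count expected if the terms were
    mentioned independently.  Support >= 1 indicates the pair co-occurs at
    least as often as chance (the evidence threshold used for calling a
    predicted association literature-supported).
    """
    if corpus_size <= 0:
        raise ValueError("corpus_size must be positive")
    if min(h_count, g_count, joint_count) < 0:
        raise ValueError("article counts must be nonnegative")
    if h_count == 0 or g_count == 0:
        raise ValueError("support is undefined when either term has zero articles")
    if joint_count > min(h_count, g_count):
        raise ValueError("joint count cannot exceed either marginal count")
    return joint_count / (h_count * g_count) * corpus_size


def embedding_cosine(v1: Sequence[float], v2: Sequence[float]) -> float:
    """Cosine similarity of two embedding vectors, in [-1, 1].

    A positive similarity between a gene symbol's and a hormone/disease
    term's embedding supports the association in the literature-derived
    embedding space.
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"vectors must share one dimension; got {a.shape}, {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))
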