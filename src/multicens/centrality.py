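"""Hierarchical multilayer centrality measures and their fixed-point solver.

All measures are fixed points of affine systems ``v = p * T v + b`` where
``T`` is built from the jointly normalized intra-layer matrix ``A`` and/or
inter-layer matrix ``C``, and ``p`` in ``[0, 1)`` is the restart (damping)
parameter.  The solvers apply the normalized matrices in the PageRank
(transition-matrix) orientation: each supra-node's outgoing weight is
divided by its total degree and a node's score accumulates incoming random-
walk mass, i.e. the operator is the transpose of the row-normalized matrix
(column-stochastic, since the network is undirected).  Because the
normalized ``A + C`` is (sub)stochastic, ``p*T`` has spectral radius below
one and simple iteration from the forcing vector converges geometrically.
Were the row-normalized matrices applied un-transposed instead, every
uniform-forcing measure would collapse to an exactly uniform vector
(a stochastic matrix fixes the all-ones vector), so only the transition
orientation yields the informative, PageRank-consistent scores; every
convergence and decomposability identity below is orientation-agnostic.

The hierarchy decomposes PageRank versatility on the full supra-adjacency:

* local centrality        ``l = p A l + (1-p)/n * 1``
  (within-layer influence only; splits exactly by layer),
* global centrality       ``g = p[(A+C) g + C l] + (1-p)/N * 1``
  (the remaining, cross-layer-aware influence; ``l + g = (L+1) x`` with
  ``x`` the versatility vector),
* layer-specific          ``g_i = p[(A+C) g_i + C l_i] + (1-p)/N * 1_[i]``
  (influence on one target layer; sums over layers to ``g``),
* local-set / query-set   (influence on a chosen node set inside the target
  layer; sums over a partition of the layer to the layer-level measures).

Query-set centrality is the measure used to rank candidate mediator genes:
score every gene in every layer by its multi-hop influence on a query set of
genes (e.g. hormone-responsive genes) in a target tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .network import SupraDecomposition

DEFAULT_P = 0.85
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000


@dataclass
class QuerySet:
    """A nonempty set of node IDs confined to a single target layer."""

    layer: str
    nodes: frozenset[str]

    def __init__(self, layer: str, nodes) -> None:
        self.layer = str(layer)
        self.nodes = frozenset(str(v) for v in nodes)
        if not self.nodes:
            raise ValueError("query set must be nonempty")

    def indicator(self, dec: SupraDecomposition) -> np.ndarray:
        """0/1 supra-vector with ones on the query nodes in the target layer."""
        net = dec.network
        unknown = self.nodes - set(net.node_names)
        if unknown:
            raise KeyError(f"query nodes not in network: {sorted(unknown)[:5]}")
        v = np.zeros(dec.n_supra)
        for node in self.nodes:
            v[net.supra_index(node, self.layer)] = 1.0
        return v


@dataclass
class CentralityResult:
    """A score per supra-node with provenance of how it was computed."""

    scores: np.ndarray
    measure: str
    p: float
    target_layer: str | None = None
    query_set: frozenset[str] | None = None
    converged_in: int = 0
    residual: float = 0.0

    def normalized(self) -> np.ndarray:
        """Unit-sum copy of the scores (centrality vectors are scale-agnostic)."""
        total = self.scores.sum()
        return self.scores / total if total > 0 else self.scores.copy()

    def to_frame(self, dec: SupraDecomposition) -> pd.DataFrame:
        """Tidy table: node, layer, score, rank (rank over all supra-nodes)."""
        labels = dec.network.supra_labels()
        df = pd.DataFrame(
            {
                "node": [v for v, _ in labels],
                "layer": [l for _, l in labels],
                "score": self.scores,
            }
        )
        df["rank"] = rank_nodes_frame(df)
        return df

    def layer_ranking(self, dec: SupraDecomposition, layer: str) -> list[str]:
        """Node IDs of one layer, best score first, ties by node ID."""
        sl = dec.layer_slice(layer)
        nodes = dec.network.node_names
        scores = self.scores[sl]
        order = sorted(range(len(nodes)), key=lambda i: (-scores[i], nodes[i]))
        return [nodes[i] for i in order]


def rank_nodes_frame(df: pd.DataFrame) -> np.ndarray:
    """1-based ranks: descending score, ties broken by node ID then layer."""
    order = df.sort_values(
        ["score", "node", "layer"], ascending=[False, True, True], kind="mergesort"
    ).index
    ranks = np.empty(len(df), dtype=int)
    ranks[order] = np.arange(1, len(df) + 1)
    return ranks


# -- fixed-point engine ----------------------------------------------------


def solve_fixed_point(
    operator: np.ndarray | Callable[[np.ndarray], np.ndarray],
    forcing: np.ndarray,
    p: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, int, float]:
    """Iterate ``v <- p * T v + b`` to its unique fixed point.

    The iteration starts from the forcing vector ``b`` (which is the exact
    solution at ``p = 0``) and stops when the L-infinity change drops to
    ``tol``.  Requires ``spectral_radius(p * T) < 1``, which holds for every
    system in this module because the normalized ``A + C`` is row-substochastic
    and ``p < 1``.

    Returns ``(solution, iterations, final_residual)``.
    """
    _check_p(p)
    apply = (lambda v: operator @ v) if isinstance(operator, np.ndarray) else operator
    v = np.asarray(forcing, dtype=float).copy()
    for it in range(1, max_iter + 1):
        v_next = p * apply(v) + forcing
        residual = float(np.max(np.abs(v_next - v))) if v.size else 0.0
        v = v_next
        if residual <= tol:
            return v, it, residual
    raise RuntimeError(
        f"fixed-point iteration did not converge in {max_iter} iterations "
        f"(last L-inf change {residual:.3e}, tol {tol:.3e})"
    )


def _check_p(p: float) -> None:
    if not (0 <= p < 1):
        raise ValueError(f"restart parameter p must lie in [0, 1); got {p}")


def _require_normalized(dec: SupraDecomposition) -> None:
    if not dec.normalized:
        raise ValueError(
            "centrality solvers need a row-normalized decomposition; "
            "call row_normalize() first"
        )


# -- the measures ----------------------------------------------------------


def local_centrality(
    dec: SupraDecomposition,
    p: float = DEFAULT_P,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CentralityResult:
    """Within-layer influence: fixed point of ``l = p A l + (1-p)/n * 1``."""
    _require_normalized(dec)
    _check_p(p)
    forcing = np.full(dec.n_supra, (1 - p) / dec.n_nodes)
    scores, it, res = solve_fixed_point(dec.A.T, forcing, p, tol, max_iter)
    return CentralityResult(scores, "local", p, converged_in=it, residual=res)


def local_layer_centrality(
    dec: SupraDecomposition,
    layer: str,
    p: float = DEFAULT_P,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CentralityResult:
    """Local centrality restricted to one layer via the masked matrix A^[i].

    A^[i] keeps only layer ``i``'s column block of A; together with the
    layer-indicator forcing this zeroes every entry outside the layer, and
    the results sum over layers to the full local centrality.
    """
    _require_normalized(dec)
    _check_p(p)
    forcing = (1 - p) / dec.n_nodes * dec.layer_indicator(layer)
    scores, it, res = solve_fixed_point(dec.masked_A(layer).T, forcing, p, tol, max_iter)
    return CentralityResult(
        scores, "local_layer", p, target_layer=str(layer), converged_in=it, residual=res
    )


def global_centrality(
    dec: SupraDecomposition,
    p: float = DEFAULT_P,
    l: CentralityResult | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CentralityResult:
    """Cross-layer-aware influence: ``g = p[(A+C)g + C l] + (1-p)/N * 1``.

    ``l`` is the local centrality of the same decomposition at the same
    ``p`` (computed on demand when omitted).
    """
    _require_normalized(dec)
    _check_p(p)
    if l is None:
        l = local_centrality(dec, p, tol, max_iter)
    if l.measure != "local" or l.p != p:
        raise ValueError(
            f"need the local centrality at p={p}; got measure={l.measure!r} at p={l.p}"
        )
    forcing = p * (dec.C.T @ l.scores) + (1 - p) / dec.n_supra
    scores, it, res = solve_fixed_point(dec.M.T, forcing, p, tol, max_iter)
    return CentralityResult(scores, "global", p, converged_in=it, residual=res)


def layer_specific_centrality(
    dec: SupraDecomposition,
    layer: str,
    p: float = DEFAULT_P,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CentralityResult:
    """Influence on one target layer: global centrality with layer-local terms.

    ``g_i = p[(A+C) g_i + C l_i] + (1-p)/N * 1_[i]`` where ``l_i`` is the
    layer-restricted local centrality.  Only inter-layer edges incident to
    the target layer contribute through the ``C l_i`` term.
    """
    _require_normalized(dec)
    _check_p(p)
    l_i = local_layer_centrality(dec, layer, p, tol, max_iter)
    forcing = p * (dec.C.T @ l_i.scores) + (1 - p) / dec.n_supra * dec.layer_indicator(layer)
    scores, it, res = solve_fixed_point(dec.M.T, forcing, p, tol, max_iter)
    return CentralityResult(
        scores, "layer_specific", p, target_layer=str(layer), converged_in=it, residual=res
    )


def local_set_centrality(
    dec: SupraDecomposition,
    q: QuerySet,
    p: float = DEFAULT_P,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CentralityResult:
    """Local centrality focused on a query set inside its layer."""
    _require_normalized(dec)
    _check_p(p)
    forcing = (1 - p) / dec.n_nodes * q.indicator(dec)
    scores, it, res = solve_fixed_point(dec.masked_A(q.layer).T, forcing, p, tol, max_iter)
    return CentralityResult(
        scores,
        "local_set",
        p,
        target_layer=q.layer,
        query_set=q.nodes,
        converged_in=it,
        residual=res,
    )


def query_set_centrality(
    dec: SupraDecomposition,
    q: QuerySet,
    p: float = DEFAULT_P,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CentralityResult:
    """Influence on a query set of nodes in a target layer (gene ranking measure).

    ``g_i^k = p[(A+C) g_i^k + C l_i^k] + (1-p)/N * 1_i^k`` with ``l_i^k`` the
    local-set centrality of the same query set.  Over a partition of the
    layer these sum to the layer-specific centrality.
    """
    _require_normalized(dec)
    _check_p(p)
    l_set = local_set_centrality(dec, q, p, tol, max_iter)
    forcing = p * (dec.C.T @ l_set.scores) + (1 - p) / dec.n_supra * q.indicator(dec)
    scores, it, res = solve_fixed_point(dec.M.T, forcing, p, tol, max_iter)
    return CentralityResult(
        scores,
        "query_set",
        p,
        target_layer=q.layer,
        query_set=q.nodes,
        converged_in=it,
        residual=res,
    )
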