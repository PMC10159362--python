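"""Comparison centralities: intra/inter-layer degree, versatility, RWR-H.

Degree baselines operate on the raw (unnormalized) weight matrices; the
inter-layer degree with -ln(p-value) edge weights is the S_sec score of
earlier endocrine-interaction work, and its query-restricted variant counts
only inter-layer weight incident to a query set.  Versatility is PageRank on
the full normalized supra-adjacency (transition orientation, like the
hierarchical measures), blind to the intra/inter distinction.  RWR-H is a
random walk with restart on column-normalized
transition matrices with an inter-layer jump probability lambda and a seed
restart vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .centrality import (
    DEFAULT_MAX_ITER,
    DEFAULT_P,
    DEFAULT_TOL,
    CentralityResult,
    QuerySet,
    _check_p,
    _require_normalized,
    solve_fixed_point,
)
from .network import SupraDecomposition

DEFAULT_LAMBDA = 0.5


@dataclass
class RWRHConfig:
    """Random-walk-with-restart configuration.

    seeds are (node, layer) pairs; the walker restarts uniformly over them
    with probability 1 - p, and at each continuation step jumps across
    layers with probability ``lam`` (default 0.5) or stays within the layer.
    """

    seeds: list[tuple[str, str]]
    p: float = DEFAULT_P
    lam: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("RWR-H needs a nonempty seed set")
        if not (0 <= self.lam <= 1):
            raise ValueError(f"lambda must lie in [0, 1]; got {self.lam}")
        _check_p(self.p)

    @classmethod
    def from_query_set(cls, q: QuerySet, p: float = DEFAULT_P, lam: float = DEFAULT_LAMBDA):
        return cls(seeds=[(v, q.layer) for v in sorted(q.nodes)], p=p, lam=lam)


def _require_raw(dec: SupraDecomposition, what: str) -> None:
    if dec.normalized:
        raise ValueError(f"{what} is defined on the unnormalized decomposition")


def intra_layer_degree(dec: SupraDecomposition) -> CentralityResult:
    """Weighted within-layer degree: row sums of the raw A."""
    _require_raw(dec, "intra-layer degree")
    return CentralityResult(dec.A.sum(axis=1), "deg_intra", p=0.0)


def inter_layer_degree(
    dec: SupraDecomposition, query: QuerySet | None = None
) -> CentralityResult:
    """Weighted cross-layer degree: row sums of the raw C.

    With ``query`` given, only columns of C belonging to the query set's
    supra-nodes are summed, i.e. only inter-layer weight pointing into the
    query set counts (the restriction used when benchmarking against a
    known query set).
    """
    _require_raw(dec, "inter-layer degree")
    if query is None:
        scores = dec.C.sum(axis=1)
        qset = None
    else:
        cols = query.indicator(dec).astype(bool)
        scores = dec.C[:, cols].sum(axis=1)
        qset = query.nodes
    return CentralityResult(scores, "deg_inter", p=0.0, query_set=qset)


def versatility(
    dec: SupraDecomposition,
    p: float = DEFAULT_P,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CentralityResult:
    """PageRank on the full supra-adjacency: ``x = p M x + (1-p)/N * 1``."""
    _require_normalized(dec)
    _check_p(p)
    forcing = np.full(dec.n_supra, (1 - p) / dec.n_supra)
    scores, it, res = solve_fixed_point(dec.M.T, forcing, p, tol, max_iter)
    return CentralityResult(scores, "versatility", p, converged_in=it, residual=res)


def rwr_h(
    dec: SupraDecomposition,
    cfg: RWRHConfig,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CentralityResult:
    """Random walk with restart on the heterogeneous/multilayer network.

    ``x = p M~ x + (1-p) x0`` with ``M~ = (1-lam) A~ + lam C~`` where A~ and
    C~ are the column-normalized A and C, and x0 puts mass 1/|S| on each
    seed.  Zero columns are left zero (mass restarting there is absorbed),
    so scores sum to at most one, with equality when no column is empty.
    """
    _require_raw(dec, "RWR-H (it column-normalizes internally)")
    net = dec.network
    A_t = _column_normalize(dec.A)
    C_t = _column_normalize(dec.C)
    M_t = (1 - cfg.lam) * A_t + cfg.lam * C_t

    x0 = np.zeros(dec.n_supra)
    for node, layer in cfg.seeds:
        x0[net.supra_index(node, layer)] = 1.0
    x0 /= x0.sum()

    scores, it, res = solve_fixed_point(M_t, (1 - cfg.p) * x0, cfg.p, tol, max_iter)
    return CentralityResult(
        scores,
        "rwr_h",
        cfg.p,
        query_set=frozenset(v for v, _ in cfg.seeds),
        converged_in=it,
        residual=res,
    )


def _column_normalize(mat: np.ndarray) -> np.ndarray:
    col_sums = mat.sum(axis=0)
    scale = np.where(col_sums > 0, col_sums, 1.0)
    return mat / scale[None, :]
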