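"""Benchmark harness tying generator, centralities and evaluation together.

Reproduces the synthetic-network study protocol: for each (model, connection
strength, ground-truth mixing fraction x, seed) the harness generates a
network, ranks the source layer's nodes with every method, and scores each
ranking against the planted ground truth by recall-at-k and normalized AUC.

Following the study protocol for query-aware baselines, inter-layer degree
and versatility are computed using inter-layer connections to the query set
only, and RWR-H's seed nodes are the query set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import baselines, centrality
from .centrality import QuerySet
from .inference import ExpressionMatrix
from .network import MultilayerNetwork, SupraDecomposition
from .synthetic import LAYER1, SyntheticConfig, SyntheticTruth, generate_synthetic

BENCHMARK_METHODS = ("qc", "lc", "gc", "versatility", "deg_inter", "rwrh")


def restrict_interlayer_to(
    net: MultilayerNetwork, query: QuerySet
) -> MultilayerNetwork:
    """Drop every inter-layer edge not incident to a query supra-node."""
    dec = net.decompose()
    keep = query.indicator(dec).astype(bool)
    C = dec.C.copy()
    mask = np.outer(~keep, ~keep)
    C[mask] = 0.0
    return MultilayerNetwork(net.layer_names, net.node_names, dec.A + C)


def rank_methods(
    net: MultilayerNetwork,
    query: QuerySet,
    rank_layer: str,
    p: float = centrality.DEFAULT_P,
    lam: float = baselines.DEFAULT_LAMBDA,
    tol: float = centrality.DEFAULT_TOL,
    max_iter: int = centrality.DEFAULT_MAX_ITER,
    methods: Sequence[str] = BENCHMARK_METHODS,
) -> dict[str, list[str]]:
    """Rank the nodes of ``rank_layer`` by each method, best first."""
    raw = net.decompose()
    dec = raw.row_normalize()
    rankings: dict[str, list[str]] = {}
    for method in methods:
        if method == "qc":
            res = centrality.query_set_centrality(dec, query, p, tol, max_iter)
        elif method == "lc":
            res = centrality.local_centrality(dec, p, tol, max_iter)
        elif method == "gc":
            res = centrality.global_centrality(dec, p, tol=tol, max_iter=max_iter)
        elif method == "versatility":
            restricted = restrict_interlayer_to(net, query).decompose().row_normalize()
            res = baselines.versatility(restricted, p, tol, max_iter)
        elif method == "deg_inter":
            res = baselines.inter_layer_degree(raw, query=query)
        elif method == "rwrh":
            cfg = baselines.RWRHConfig.from_query_set(query, p=p, lam=lam)
            res = baselines.rwr_h(raw, cfg, tol, max_iter)
        else:
            raise ValueError(f"unknown benchmark method {method!r}")
        rankings[method] = res.layer_ranking(dec, rank_layer)
    return rankings


def run_benchmark(
    models: Sequence[int] = (1, 2),
    strengths: Sequence[float] = tuple(np.arange(1, 21) * 0.05),
    xs: Sequence[float] = (0.0, 0.5, 1.0),
    seeds: Sequence[int] = (0,),
    n_per_layer: int = 500,
    community_size: int = 50,
    base_p: float = 0.05,
    recall_k: int = 100,
    p: float = centrality.DEFAULT_P,
    lam: float = baselines.DEFAULT_LAMBDA,
    methods: Sequence[str] = BENCHMARK_METHODS,
) -> pd.DataFrame:
    """Full sweep; one row per (model, strength, x, method, seed).

    Columns: model, strength, x, method, seed, recall_at_k, auc.  The ranked
    universe is the whole source layer (layer 1), where the planted ground
    truth lives.
    """
    from .evaluation import recall_at_k as _recall_curve

    rows = []
    for model in models:
        for strength in strengths:
            for x in xs:
                for seed in seeds:
                    cfg = SyntheticConfig(
                        model=model,
                        n_per_layer=n_per_layer,
                        base_p=base_p,
                        community_size=community_size,
                        strength=float(strength),
                        seed=int(seed),
                    )
                    net, truth = generate_synthetic(cfg, fraction_x=float(x))
                    rankings = rank_methods(
                        net, truth.query_set, LAYER1, p=p, lam=lam, methods=methods
                    )
                    gt = set(truth.ground_truth)
                    for method, ranking in rankings.items():
                        ev = _recall_curve(ranking, gt)
                        rows.append(
                            {
                                "model": model,
                                "strength": float(strength),
                                "x": float(x),
                                "method": method,
                                "seed": int(seed),
                                f"recall_at_{recall_k}": ev.recall_at(recall_k),
                                "auc": ev.auc,
                            }
                        )
    return pd.DataFrame(rows)


def generate_fixture_expression(
    n_genes: int,
    n_samples: int,
    n_tissues: int = 2,
    module_size: int = 10,
    module_rho: float = 0.9,
    seed: int = 0,
) -> list[ExpressionMatrix]:
    """Gaussian expression with one planted module correlated across tissues.

    The first ``module_size`` genes of every tissue load on a shared
    per-sample latent factor so that each pair of module genes -- within a
    tissue or across tissues -- has population correlation ``module_rho``;
    all other genes are independent noise.  All tissues share the same
    subject IDs, so cross-layer correlations are computed on every sample.
    """
    if min(n_genes, n_samples) < 2 or n_tissues < 2:
        raise ValueError("need n_genes, n_samples >= 2 and n_tissues >= 2")
    if not (0 <= module_rho <= 1):
        raise ValueError(f"module_rho must lie in [0, 1]; got {module_rho}")
    if module_size > n_genes:
        raise ValueError("module_size cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    samples = [f"s{i:04d}" for i in range(n_samples)]
    factor = rng.standard_normal(n_samples)
    out = []
    for t in range(n_tissues):
        noise = rng.standard_normal((n_genes, n_samples))
        values = noise.copy()
        values[:module_size] = (
            np.sqrt(module_rho) * factor
            + np.sqrt(1 - module_rho) * noise[:module_size]
        )
        out.append(ExpressionMatrix(f"tissue{t + 1}", genes, samples, values))
    return out
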