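"""Two-layer benchmark networks with planted communities and ground truth.

The generator emulates a hormone-signaling scenario: a query set of
"hormone-responsive" nodes in layer 2, a community *source set 1* in layer 1
directly connected to it, and a community *source set 2* reachable from the
query set only through source set 1 (two hops).  Construction:

1. Base network: every within- and cross-layer node pair gets an edge with
   probability ``base_p`` (0.05), weight one.
2. Extra edges at probability ``strength`` (the *connection strength*)
   within the query set, within each source set, between source set 1 and
   source set 2, and -- cross-layer -- between source set 1 and the query
   set.  A pair hit by both the base and the extra pass gets weight two.
3. Three decoy background communities (in layer 1 by default) with extra
   edges within and between all pairs of them at ``background_strength``.
   Each background node then carries roughly as much community weight as a
   source-set-1 node, so degree alone cannot separate signal from decoys.
4. Model 2 adds one more layer-2 community with extra edges within itself
   and to the query set, crowding the query set's neighborhood.

The benchmark ground truth mixes the two source sets: a fraction ``x`` of
the ``community_size`` ground-truth slots is drawn from source set 2 (the
two-hop community), the rest from source set 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centrality import QuerySet
from .network import MultilayerNetwork

LAYER1 = "layer1"
LAYER2 = "layer2"


@dataclass
class SyntheticConfig:
    """Knobs of the benchmark generator; defaults are the study conditions."""

    model: int = 1
    n_per_layer: int = 500
    base_p: float = 0.05
    community_size: int = 50
    strength: float = 0.5
    background_strength: float | None = None  # None -> same as strength
    background_layer: str = LAYER1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in (1, 2):
            raise ValueError(f"model must be 1 or 2; got {self.model}")
        for name in ("base_p", "strength"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if self.background_strength is not None and not (0 <= self.background_strength <= 1):
            raise ValueError("background_strength must lie in [0, 1]")
        cs = self.community_size
        layer1_comms = 2 + (3 if self.background_layer == LAYER1 else 0)
        layer2_comms = (1 if self.model == 1 else 2) + (
            3 if self.background_layer == LAYER2 else 0
        )
        if cs * max(layer1_comms, layer2_comms) > self.n_per_layer:
            raise ValueError(
                f"community_size={cs} communities do not fit in "
                f"n_per_layer={self.n_per_layer}"
            )

    @property
    def bg_strength(self) -> float:
        return self.strength if self.background_strength is None else self.background_strength


@dataclass
class SyntheticTruth:
    """Named planted node sets of one generated network."""

    query_set: QuerySet
    source_set_1: list[str]
    source_set_2: list[str]
    background_sets: list[list[str]]
    extra_layer2_community: list[str]
    ground_truth: list[str]

    def as_dict(self) -> dict:
        return {
            "query_layer": self.query_set.layer,
            "query_set": sorted(self.query_set.nodes),
            "source_set_1": self.source_set_1,
            "source_set_2": self.source_set_2,
            "background_sets": self.background_sets,
            "extra_layer2_community": self.extra_layer2_community,
            "ground_truth": self.ground_truth,
        }


def generate_synthetic(
    cfg: SyntheticConfig, fraction_x: float = 0.0
) -> tuple[MultilayerNetwork, SyntheticTruth]:
    """Generate one benchmark network plus its planted structure.

    Deterministic for a fixed config: the same seed yields a bitwise
    identical supra-adjacency and ground truth.
    """
    n, cs = cfg.n_per_layer, cfg.community_size
    rng = np.random.default_rng(cfg.seed)
    node_names = [f"g{i:04d}" for i in range(n)]
    layers = [LAYER1, LAYER2]
    N = 2 * n

    # contiguous first-fit community blocks, reproducible by construction
    src1 = np.arange(0, cs)
    src2 = np.arange(cs, 2 * cs)
    next_l1 = 2 * cs
    query = n + np.arange(0, cs)  # layer-2 supra indices
    extra2 = np.arange(cs, 2 * cs) + n if cfg.model == 2 else np.array([], dtype=int)
    next_l2 = (2 if cfg.model == 2 else 1) * cs
    if cfg.background_layer == LAYER1:
        bg = [np.arange(next_l1 + k * cs, next_l1 + (k + 1) * cs) for k in range(3)]
    else:
        bg = [n + np.arange(next_l2 + k * cs, next_l2 + (k + 1) * cs) for k in range(3)]

    M = np.zeros((N, N))
    iu = np.triu_indices(N, k=1)
    base = rng.random(len(iu[0])) < cfg.base_p
    M[iu] = base.astype(float)

    def add_extra(rows: np.ndarray, cols: np.ndarray, prob: float) -> None:
        """Extra ER edges between two index sets (or within one if identical)."""
        if prob == 0 or len(rows) == 0 or len(cols) == 0:
            return
        if rows is cols or np.array_equal(rows, cols):
            rr, cc = np.triu_indices(len(rows), k=1)
            pairs = np.stack([rows[rr], rows[cc]], axis=1)
        else:
            pairs = np.stack(
                [np.repeat(rows, len(cols)), np.tile(cols, len(rows))], axis=1
            )
        hit = rng.random(len(pairs)) < prob
        for i, j in pairs[hit]:
            a, b = (i, j) if i < j else (j, i)
            M[a, b] += 1.0  # base + extra overlap -> weight two

    s, bs = cfg.strength, cfg.bg_strength
    add_extra(query, query, s)
    add_extra(src1, src1, s)
    add_extra(src2, src2, s)
    add_extra(src1, src2, s)
    add_extra(src1, query, s)  # direct cross-layer link to the query set
    if cfg.model == 2:
        add_extra(extra2, extra2, s)
        add_extra(extra2, query, s)
    for k in range(3):
        add_extra(bg[k], bg[k], bs)
        for k2 in range(k + 1, 3):
            add_extra(bg[k], bg[k2], bs)

    M = M + M.T
    net = MultilayerNetwork(layers, node_names, M)

    name = lambda idx: [node_names[i % n] for i in idx]
    truth_sets = SyntheticTruth(
        query_set=QuerySet(LAYER2, name(query)),
        source_set_1=name(src1),
        source_set_2=name(src2),
        background_sets=[name(b) for b in bg],
        extra_layer2_community=name(extra2),
        ground_truth=[],
    )
    truth_sets.ground_truth = make_ground_truth(truth_sets, fraction_x, cfg.seed)
    return net, truth_sets


def make_ground_truth(
    truth: SyntheticTruth, fraction_x: float, seed: int
) -> list[str]:
    """Mix of the two source communities: floor(x * size) two-hop nodes.

    Draws ``floor(x * community_size)`` nodes from source set 2 and the
    complement from source set 1, each without replacement, deterministically
    under ``seed``.  ``x = 0`` reproduces source set 1 exactly; ``x = 1``
    reproduces source set 2.
    """
    if not (0 <= fraction_x <= 1):
        raise ValueError(f"fraction_x must lie in [0, 1]; got {fraction_x}")
    size = len(truth.source_set_1)
    n2 = int(np.floor(fraction_x * size))
    n1 = size - n2
    rng = np.random.default_rng(seed)
    pick1 = sorted(rng.choice(truth.source_set_1, size=n1, replace=False).tolist())
    pick2 = sorted(rng.choice(truth.source_set_2, size=n2, replace=False).tolist())
    return pick1 + pick2
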