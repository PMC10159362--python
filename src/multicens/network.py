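"""Weighted multilayer networks and their supra-adjacency decomposition.

A multilayer network has the same ordered node set replicated across ``L``
layers (here layers are typically tissues or brain regions and nodes are
genes).  All edges -- within a layer or between any pair of node replicas in
two different layers -- live in a single symmetric nonnegative supra-adjacency
matrix ``M`` of size ``N x N`` with ``N = n * L``.  ``M`` splits into a
block-diagonal intra-layer part ``A`` and an off-block inter-layer part ``C``
with ``M = A + C``; all centrality measures in this package are defined in
terms of these two matrices.

Supra-index convention: node ``i`` in layer ``alpha`` sits at flat index
``alpha * n + i``, layers in declared order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EDGELIST_COLUMNS = ["node_a", "layer_a", "node_b", "layer_b", "weight"]


@dataclass
class MultilayerNetwork:
    """A weighted undirected multilayer network.

    Parameters
    ----------
    layer_names:
        Ordered layer identifiers (length ``L``).
    node_names:
        Ordered node identifiers (length ``n``), identical across layers.
    M:
        Dense symmetric nonnegative supra-adjacency matrix of shape
        ``(n*L, n*L)`` with zero diagonal.
    """

    layer_names: list[str]
    node_names: list[str]
    M: np.ndarray

    def __post_init__(self) -> None:
        self.layer_names = [str(x) for x in self.layer_names]
        self.node_names = [str(x) for x in self.node_names]
        self.M = np.asarray(self.M, dtype=float)
        N = self.n_nodes * self.n_layers
        if self.M.shape != (N, N):
            raise ValueError(
                f"supra-adjacency must be {N}x{N} for n={self.n_nodes}, "
                f"L={self.n_layers}; got {self.M.shape}"
            )
        if (self.M < 0).any():
            raise ValueError("edge weights must be nonnegative")
        if not np.allclose(self.M, self.M.T):
            raise ValueError("supra-adjacency must be symmetric (undirected network)")
        if np.abs(np.diag(self.M)).max(initial=0.0) > 0:
            raise ValueError("self-edges are not allowed (diagonal must be zero)")
        self._layer_index = {name: a for a, name in enumerate(self.layer_names)}
        self._node_index = {name: i for i, name in enumerate(self.node_names)}

    # -- index bookkeeping -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        """Number of nodes per layer (``n``)."""
        return len(self.node_names)

    @property
    def n_layers(self) -> int:
        """Number of layers (``L``)."""
        return len(self.layer_names)

    @property
    def n_supra(self) -> int:
        """Total number of supra-nodes ``N = n * L``."""
        return self.n_nodes * self.n_layers

    def layer_offset(self, layer: str) -> int:
        try:
            return self._layer_index[str(layer)] * self.n_nodes
        except KeyError:
            raise KeyError(
                f"unknown layer {layer!r}; declared layers: {self.layer_names}"
            ) from None

    def layer_slice(self, layer: str) -> slice:
        """Slice of supra-indices belonging to one layer."""
        off = self.layer_offset(layer)
        return slice(off, off + self.n_nodes)

    def supra_index(self, node: str, layer: str) -> int:
        """Flat index of (node, layer): ``layer_pos * n + node_pos``."""
        off = self.layer_offset(layer)
        try:
            return off + self._node_index[str(node)]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def supra_labels(self) -> list[tuple[str, str]]:
        """(node, layer) pair for every supra-index, in order."""
        return [(v, l) for l in self.layer_names for v in self.node_names]

    # -- structure ---------------------------------------------------------

    def decompose(self) -> "SupraDecomposition":
        """Split ``M`` into intra-layer ``A`` and inter-layer ``C`` blocks."""
        return decompose(self)

    def prune(self, threshold: float) -> "MultilayerNetwork":
        """Zero out every edge with weight strictly below ``threshold``."""
        M = self.M.copy()
        M[M < threshold] = 0.0
        return MultilayerNetwork(self.layer_names, self.node_names, M)

    def edge_iter(self) -> Iterable[tuple[str, str, str, str, float]]:
        """Yield each undirected edge once (upper triangle), declared order."""
        n = self.n_nodes
        rows, cols = np.nonzero(np.triu(self.M))
        for r, c in zip(rows.tolist(), cols.tolist()):
            yield (
                self.node_names[r % n],
                self.layer_names[r // n],
                self.node_names[c % n],
                self.layer_names[c // n],
                float(self.M[r, c]),
            )


@dataclass
class SupraDecomposition:
    """``M = A + C`` with A block-diagonal (intra-layer) and C off-block.

    ``normalized`` records whether A and C are the blocks of the jointly
    row-normalized M: each positive row of ``A + C`` sums to one, zero rows
    stay zero.  The centrality solvers require the normalized form; the raw
    degree baselines require the unnormalized one.
    """

    network: MultilayerNetwork
    A: np.ndarray
    C: np.ndarray
    normalized: bool = False

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes

    @property
    def n_layers(self) -> int:
        return self.network.n_layers

    @property
    def n_supra(self) -> int:
        return self.network.n_supra

    @property
    def M(self) -> np.ndarray:
        return self.A + self.C

    def layer_slice(self, layer: str) -> slice:
        return self.network.layer_slice(layer)

    def layer_indicator(self, layer: str) -> np.ndarray:
        """0/1 vector selecting the supra-nodes of one layer."""
        v = np.zeros(self.n_supra)
        v[self.layer_slice(layer)] = 1.0
        return v

    def masked_A(self, layer: str) -> np.ndarray:
        """``A`` with all but ``layer``'s column block zeroed (``A^[i]``)."""
        out = np.zeros_like(self.A)
        sl = self.layer_slice(layer)
        out[:, sl] = self.A[:, sl]
        return out

    def row_normalize(self) -> "SupraDecomposition":
        return row_normalize(self)


def decompose(net: MultilayerNetwork) -> SupraDecomposition:
    """Split the supra-adjacency into intra-layer A and inter-layer C.

    A holds exactly the L diagonal ``n x n`` blocks of M, C the off-diagonal
    blocks, so ``A + C == M`` entrywise.
    """
    n, L = net.n_nodes, net.n_layers
    A = np.zeros_like(net.M)
    for a in range(L):
        sl = slice(a * n, (a + 1) * n)
        A[sl, sl] = net.M[sl, sl]
    C = net.M - A
    return SupraDecomposition(network=net, A=A, C=C, normalized=False)


def row_normalize(dec: SupraDecomposition) -> SupraDecomposition:
    """Jointly row-normalize so each positive row of ``A + C`` sums to one.

    A and C rows are scaled by the same factor (the row sum of ``A + C``) so
    the block structure is preserved; zero rows (isolated supra-nodes) are
    left as all zeros, which is safe because every solver's linear operator
    then has spectral radius at most the restart parameter ``p < 1``.
    """
    if dec.normalized:
        raise ValueError("decomposition is already row-normalized")
    row_sums = dec.A.sum(axis=1) + dec.C.sum(axis=1)
    scale = np.where(row_sums > 0, row_sums, 1.0)
    return SupraDecomposition(
        network=dec.network,
        A=dec.A / scale[:, None],
        C=dec.C / scale[:, None],
        normalized=True,
    )


# -- edge-list I/O ---------------------------------------------------------


def read_multilayer_edgelist(
    path,
    layer_names: Sequence[str],
    node_names: Sequence[str] | None = None,
) -> MultilayerNetwork:
    """Read a TSV edge list (node_a, layer_a, node_b, layer_b, weight).

    The file must have a header row; lines starting with '#' are comments.
    Each undirected edge may be listed once (either orientation) and is
    stored symmetrically.  If ``node_names`` is omitted, the sorted union of
    observed node IDs is used and replicated in every layer.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in EDGELIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge list {path} is missing columns {missing}")
    df = df[EDGELIST_COLUMNS]
    layer_names = [str(x) for x in layer_names]
    layer_set = set(layer_names)
    for col in ("layer_a", "layer_b"):
        bad = df.index[~df[col].isin(layer_set)]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValueError(
                f"row {bad[0]}: unknown layer {row[col]!r} "
                f"(declared layers: {layer_names})"
            )
    weights = pd.to_numeric(df["weight"], errors="raise").to_numpy(dtype=float)
    if (weights < 0).any():
        bad = int(np.nonzero(weights < 0)[0][0])
        raise ValueError(f"row {bad}: negative weight {weights[bad]}")

    if node_names is None:
        node_names = sorted(set(df["node_a"]) | set(df["node_b"]))
    node_names = [str(x) for x in node_names]

    n, L = len(node_names), len(layer_names)
    node_idx = {v: i for i, v in enumerate(node_names)}
    layer_idx = {l: a for a, l in enumerate(layer_names)}
    M = np.zeros((n * L, n * L))
    seen: set[tuple[int, int]] = set()
    for pos, (na, la, nb, lb, w) in enumerate(
        zip(df["node_a"], df["layer_a"], df["node_b"], df["layer_b"], weights)
    ):
        try:
            i = layer_idx[la] * n + node_idx[na]
            j = layer_idx[lb] * n + node_idx[nb]
        except KeyError as exc:
            raise ValueError(f"row {pos}: node {exc.args[0]!r} not in node list") from None
        if i == j:
            raise ValueError(f"row {pos}: self-edge ({na}, {la})")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(
                f"row {pos}: duplicate edge ({na},{la})-({nb},{lb}); "
                "weights must be pre-aggregated"
            )
        seen.add(key)
        M[i, j] = w
        M[j, i] = w
    return MultilayerNetwork(list(layer_names), node_names, M)


def write_multilayer_edgelist(net: MultilayerNetwork, path) -> None:
    """Write each undirected edge once, weights at 12 significant digits."""
    with open(path, "w") as fh:
        fh.write("\t".join(EDGELIST_COLUMNS) + "\n")
        for na, la, nb, lb, w in net.edge_iter():
            fh.write(f"{na}\t{la}\t{nb}\t{lb}\t{w:.12g}\n")


def read_id_list(path) -> list[str]:
    """Plain-text manifest: one identifier per line, '#' comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
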