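"""Independent dense linear-algebra oracles for every centrality measure.

These rebuild the normalized operators from the raw supra-adjacency and
solve (I - p*Op) v = forcing directly with LAPACK, sharing no code with the
package's iterative solvers.
"""

import numpy as np

from multicens import MultilayerNetwork


def split_raw(net: MultilayerNetwork):
    n, L = net.n_nodes, net.n_layers
    A = np.zeros_like(net.M)
    for a in range(L):
        sl = slice(a * n, (a + 1) * n)
        A[sl, sl] = net.M[sl, sl]
    return A, net.M - A


def transition(mat: np.ndarray, row_sums: np.ndarray) -> np.ndarray:
    """Transpose of the jointly row-normalized matrix (the solver operator)."""
    scale = np.where(row_sums > 0, row_sums, 1.0)
    return (mat / scale[:, None]).T


def _solve(op: np.ndarray, forcing: np.ndarray, p: float) -> np.ndarray:
    N = op.shape[0]
    return np.linalg.solve(np.eye(N) - p * op, forcing)


def layer_mask(net: MultilayerNetwork, layer: str) -> np.ndarray:
    v = np.zeros(net.n_supra)
    v[net.layer_slice(layer)] = 1.0
    return v


def node_indicator(net: MultilayerNetwork, layer: str, nodes) -> np.ndarray:
    v = np.zeros(net.n_supra)
    for node in nodes:
        v[net.supra_index(node, layer)] = 1.0
    return v


def oracle_all(net: MultilayerNetwork, p: float, layer: str, query_nodes):
    """Direct solves for every measure on one network."""
    n, N = net.n_nodes, net.n_supra
    A, C = split_raw(net)
    deg = net.M.sum(axis=1)
    At, Ct, Mt = transition(A, deg), transition(C, deg), transition(net.M, deg)

    def masked_At(lay):
        masked = np.zeros_like(A)
        sl = net.layer_slice(lay)
        masked[:, sl] = A[:, sl]
        return transition(masked, deg)

    out = {}
    out["local"] = _solve(At, np.full(N, (1 - p) / n), p)
    out["local_layer"] = _solve(masked_At(layer), (1 - p) / n * layer_mask(net, layer), p)
    out["global"] = _solve(Mt, p * Ct @ out["local"] + (1 - p) / N, p)
    out["layer_specific"] = _solve(
        Mt, p * Ct @ out["local_layer"] + (1 - p) / N * layer_mask(net, layer), p
    )
    ind = node_indicator(net, layer, query_nodes)
    out["local_set"] = _solve(masked_At(layer), (1 - p) / n * ind, p)
    out["query_set"] = _solve(Mt, p * Ct @ out["local_set"] + (1 - p) / N * ind, p)
    out["versatility"] = _solve(Mt, np.full(N, (1 - p) / N), p)
    return out


def oracle_rwr_h(net: MultilayerNetwork, p: float, lam: float, seeds) -> np.ndarray:
    """Direct solve of the RWR-H system (per-matrix column normalization)."""
    A, C = split_raw(net)

    def colnorm(mat):
        s = mat.sum(axis=0)
        return mat / np.where(s > 0, s, 1.0)[None, :]

    Mt = (1 - lam) * colnorm(A) + lam * colnorm(C)
    x0 = np.zeros(net.n_supra)
    for node, lay in seeds:
        x0[net.supra_index(node, lay)] = 1.0
    x0 /= x0.sum()
    return _solve(Mt, (1 - p) * x0, p)


def rel_linf(a: np.ndarray, b: np.ndarray) -> float:
    scale = np.max(np.abs(b))
    if scale == 0:
        return float(np.max(np.abs(a - b)))
    return float(np.max(np.abs(a - b)) / scale)
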