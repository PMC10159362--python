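"""Multi-tissue coexpression network construction from expression matrices.

Each tissue contributes one layer.  Within-layer edge weights are absolute
Spearman correlations over that tissue's samples; cross-layer weights are
absolute Spearman correlations over the subjects shared by the two tissues
(sample IDs are subject-level, so alignment is by ID intersection).  The
resulting complete weighted graph feeds the centrality solvers directly; an
optional protein-protein interaction list adds one unit of weight to every
annotated within-layer pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import MultilayerNetwork

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values for one tissue."""

    tissue: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values must be genes x samples = "
                f"{(len(self.genes), len(self.samples))}; got {self.values.shape}"
            )
        if np.isnan(self.values).any():
            raise ValueError(f"tissue {self.tissue!r}: missing values in expression")

    @classmethod
    def from_file(cls, path, tissue: str | None = None) -> "ExpressionMatrix":
        """TSV/CSV with gene IDs in the first column, samples in the header."""
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if tissue is None:
            import os

            tissue = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(tissue, list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in set(self.genes)]
        idx = {g: i for i, g in enumerate(self.genes)}
        return ExpressionMatrix(
            self.tissue, keep, self.samples, self.values[[idx[g] for g in keep]]
        )


def top_variance_genes(xm: ExpressionMatrix, k: int) -> list[str]:
    """The ``k`` genes with largest sample variance; ties by gene-ID order."""
    if k <= 0:
        raise ValueError(f"k must be positive; got {k}")
    if k > len(xm.genes):
        raise ValueError(f"k={k} exceeds the {len(xm.genes)} genes in {xm.tissue!r}")
    variances = xm.values.var(axis=1, ddof=1)
    order = sorted(range(len(xm.genes)), key=lambda i: (-variances[i], xm.genes[i]))
    return [xm.genes[i] for i in order[:k]]


def spearman_multilayer(
    xms: Sequence[ExpressionMatrix],
    genes: Sequence[str] | None = None,
    min_shared_samples: int = 3,
) -> MultilayerNetwork:
    """Complete weighted multilayer network of |Spearman rho| edge weights.

    Within-layer correlations use all of that tissue's samples; cross-layer
    correlations use the subjects present in both tissues.  The node set is
    the (sorted) union of the given genes across layers; a gene absent from
    a tissue's matrix gets zero rows in that layer.  Correlations involving
    a constant profile are undefined and stored as weight zero.
    """
    if len(xms) < 2:
        raise ValueError("need at least two expression matrices (layers)")
    layer_names = [xm.tissue for xm in xms]
    if len(set(layer_names)) != len(layer_names):
        raise ValueError(f"duplicate tissue names: {layer_names}")
    if genes is None:
        genes = sorted(set().union(*(xm.genes for xm in xms)))
    else:
        genes = sorted({str(g) for g in genes})
    n, L = len(genes), len(xms)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # per-tissue expression aligned to the union gene list (NaN = absent)
    aligned = []
    for xm in xms:
        mat = np.full((n, len(xm.samples)), np.nan)
        for i, g in enumerate(xm.genes):
            if g in gene_pos:
                mat[gene_pos[g]] = xm.values[i]
        aligned.append(mat)

    M = np.zeros((n * L, n * L))
    for a in range(L):
        sl_a = slice(a * n, (a + 1) * n)
        M[sl_a, sl_a] = _abs_spearman_block(aligned[a], aligned[a])
        np.fill_diagonal(M[sl_a, sl_a], 0.0)
        for b in range(a + 1, L):
            shared = sorted(set(xms[a].samples) & set(xms[b].samples))
            if len(shared) < min_shared_samples:
                raise ValueError(
                    f"layers {layer_names[a]!r} and {layer_names[b]!r} share only "
                    f"{len(shared)} samples (< {min_shared_samples})"
                )
            ia = [xms[a].samples.index(s) for s in shared]
            ib = [xms[b].samples.index(s) for s in shared]
            block = _abs_spearman_block(aligned[a][:, ia], aligned[b][:, ib])
            sl_b = slice(b * n, (b + 1) * n)
            M[sl_a, sl_b] = block
            M[sl_b, sl_a] = block.T
    return MultilayerNetwork(layer_names, genes, M)


def _abs_spearman_block(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Spearman rho| between all rows of x and all rows of y.

    Rows that are entirely NaN (absent gene) or constant yield zeros.
    """
    rx, okx = _rank_rows(x)
    ry, oky = _rank_rows(y)
    with np.errstate(invalid="ignore"):
        rho = _row_pearson(rx, ry)
    rho[~okx, :] = 0.0
    rho[:, ~oky] = 0.0
    return np.abs(np.nan_to_num(rho, nan=0.0))


def _rank_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = ~np.isnan(x).any(axis=1)
    ranks = np.zeros_like(x)
    if ok.any():
        ranks[ok] = stats.rankdata(x[ok], axis=1)
    constant = np.ptp(x, axis=1) == 0
    ok &= ~constant
    return ranks, ok


def _row_pearson(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    cx = rx - rx.mean(axis=1, keepdims=True)
    cy = ry - ry.mean(axis=1, keepdims=True)
    num = cx @ cy.T
    denom = np.sqrt(np.outer((cx**2).sum(axis=1), (cy**2).sum(axis=1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / denom


def augment_with_ppi(
    net: MultilayerNetwork, ppi_edges: Sequence[tuple[str, str]]
) -> MultilayerNetwork:
    """Add one weight unit to every listed gene pair in every layer.

    Pairs referencing genes not in the network are skipped (count logged);
    duplicate listings of the same unordered pair are applied once.
    """
    known = set(net.node_names)
    idx = {g: i for i, g in enumerate(net.node_names)}
    M = net.M.copy()
    n = net.n_nodes
    seen: set[tuple[int, int]] = set()
    skipped = 0
    for ga, gb in ppi_edges:
        ga, gb = str(ga), str(gb)
        if ga not in known or gb not in known or ga == gb:
            skipped += 1
            continue
        i, j = idx[ga], idx[gb]
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        for a in range(net.n_layers):
            M[a * n + i, a * n + j] += 1.0
            M[a * n + j, a * n + i] += 1.0
    if skipped:
        logger.info("augment_with_ppi: skipped %d pairs with unknown genes", skipped)
    return MultilayerNetwork(net.layer_names, net.node_names, M)


def read_ppi_edgelist(path) -> list[tuple[str, str]]:
    """Two-column TSV of gene pairs; header optional, '#' comments allowed."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 0 and parts[:2] in (["gene_a", "gene_b"], ["node_a", "node_b"]):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno} has fewer than two columns")
            pairs.append((parts[0], parts[1]))
    return pairs


def adjust_covariates(
    xm: ExpressionMatrix, covariates: pd.DataFrame
) -> ExpressionMatrix:
    """Per-gene least-squares residuals against a covariate design.

    Non-numeric covariate columns are one-hot encoded (first level dropped);
    an intercept is always included and each gene's mean is restored, so
    covariates orthogonal to a profile leave it unchanged.
    """
    cov = covariates.loc[xm.samples]
    if cov.isna().any().any():
        raise ValueError("covariate table has missing values for some samples")
    design_parts = [pd.Series(1.0, index=cov.index, name="intercept")]
    for col in cov.columns:
        if pd.api.types.is_numeric_dtype(cov[col]):
            design_parts.append(cov[col].astype(float))
        else:
            design_parts.append(pd.get_dummies(cov[col], prefix=col, drop_first=True,
                                               dtype=float))
    X = pd.concat(design_parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = _collinear_columns(X)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {collinear}")
    Xv = X.to_numpy()
    beta, *_ = np.linalg.lstsq(Xv, xm.values.T, rcond=None)
    resid = xm.values - (Xv @ beta).T
    resid += xm.values.mean(axis=1, keepdims=True)
    return ExpressionMatrix(xm.tissue, xm.genes, xm.samples, resid)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    kept: list[int] = []
    bad: list[str] = []
    for j in range(X.shape[1]):
        cand = X.iloc[:, kept + [j]].to_numpy()
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(str(X.columns[j]))
    return bad
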