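"""QC, normalization, feature selection, PCA and graph clustering for
gene x cell count matrices (the RNA arm of the pipeline).

Conventions pinned here:

* QC boundaries: cells with fewer than ``min_features`` or more than
  ``max_features`` detected genes are removed (500 and 6000 themselves are
  kept); a mitochondrial fraction at or above ``max_mito_frac`` removes the
  cell (10.0% exactly is removed).
* Normalization: counts are scaled to ``scale_factor`` per cell and
  natural-log transformed with pseudocount 1.
* Highly variable genes: a vst-style clipped standardized variance rank
  against a robust unit-slope mean-variance trend (no loess), ties broken
  by gene id.
* Clustering: shared-nearest-neighbor Jaccard graph (k=20) on the PCA
  embedding, modularity optimization (seeded Leiden) at a given resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CountMatrix",
    "QCParams",
    "NormalizedMatrix",
    "HVGParams",
    "Embedding",
    "ClusterLabels",
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "embed_pca",
    "cluster_cells",
]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"duplicate {what}")


@dataclass
class CountMatrix:
    """Sparse nonnegative gene x cell integer counts with sample labels."""

    X: sp.csr_matrix  # genes x cells
    gene_ids: np.ndarray
    barcodes: np.ndarray
    sample_labels: np.ndarray  # per barcode

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.sample_labels = np.asarray(self.sample_labels, dtype=object)
        if self.X.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("matrix shape inconsistent with gene/barcode labels")
        if len(self.sample_labels) != len(self.barcodes):
            raise ValueError("one sample label per barcode required")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.barcodes, "barcodes")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.X[:, mask], self.gene_ids,
                           self.barcodes[mask], self.sample_labels[mask])


@dataclass
class QCParams:
    mito_prefix: str = "MT-"
    max_mito_frac: float = 0.10
    min_features: int = 500
    max_features: int = 6000

    def __post_init__(self) -> None:
        if not (0 < self.min_features < self.max_features):
            raise ValueError("need 0 < min_features < max_features")
        if not (0 < self.max_mito_frac <= 1):
            raise ValueError("max_mito_frac must lie in (0, 1]")


@dataclass
class NormalizedMatrix:
    """ln(1 + scale_factor * count / cell_total); zero iff the raw count is zero."""

    values: sp.csr_matrix  # genes x cells
    gene_ids: np.ndarray
    barcodes: np.ndarray
    scale_factor: float = 10_000.0
    sample_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class HVGParams:
    n_hvg: int = 2000
    clip: float | None = None  # default sqrt(n_cells)


@dataclass
class Embedding:
    coordinates: np.ndarray  # cells x dims
    barcodes: np.ndarray
    explained_variance_ratio: np.ndarray | None = None


@dataclass
class ClusterLabels:
    labels: np.ndarray  # int per barcode, contiguous from 0
    barcodes: np.ndarray
    resolution: float
    seed: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.barcodes, name="cluster")


def qc_filter(m: CountMatrix, p: QCParams | None = None) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove low-quality cells; returns the filtered matrix and a per-cell report.

    Kept cells satisfy min_features <= detected genes <= max_features and
    mitochondrial fraction < max_mito_frac.
    """
    p = p or QCParams()
    X = m.X.tocsc()
    detected = np.asarray((X > 0).sum(axis=0)).ravel()
    totals = np.asarray(X.sum(axis=0)).ravel().astype(float)
    mito_mask = np.array([str(g).startswith(p.mito_prefix) for g in m.gene_ids])
    if not mito_mask.any():
        warnings.warn(f"no genes with prefix {p.mito_prefix!r}; mito fraction set to 0")
        mito_counts = np.zeros(m.n_cells)
    else:
        mito_counts = np.asarray(X[mito_mask].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)
    keep = (detected >= p.min_features) & (detected <= p.max_features) & (mito_frac < p.max_mito_frac)
    if not keep.any():
        warnings.warn("QC removed every cell")
    report = pd.DataFrame({
        "barcode": m.barcodes,
        "n_features": detected,
        "total_counts": totals,
        "mito_frac": mito_frac,
        "kept": keep,
    })
    return m.subset_cells(keep), report


def normalize_log(m: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Per-cell depth normalization to ``scale_factor`` followed by ln(1+x)."""
    totals = np.asarray(m.X.sum(axis=0)).ravel().astype(float)
    if np.any(totals == 0):
        bad = m.barcodes[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total count; filter before normalizing")
    X = m.X.tocsc().astype(float)
    X = X.multiply(scale_factor / totals[None, :]).tocsr()
    X.data = np.log1p(X.data)
    return NormalizedMatrix(X, m.gene_ids, m.barcodes, scale_factor, m.sample_labels)


def select_hvg(nm: NormalizedMatrix, p: HVGParams | None = None) -> list[str]:
    """Rank genes by clipped standardized variance under a fitted trend.

    Works on the back-transformed (depth-normalized count) scale. The
    mean-variance trend is a unit-slope line in log10-log10 space (the
    Poisson-consistent slope on this scale) with a trimmed-median intercept,
    so the many trend-consistent genes anchor it and variable genes cannot
    drag their own expectation upward. Values are standardized by the trend,
    clipped at sqrt(n_cells), and genes are ranked by the variance of the
    clipped standardized values. Deterministic; ties broken by lexicographic
    gene id.
    """
    p = p or HVGParams()
    n_genes, n_cells = nm.values.shape
    if p.n_hvg > n_genes:
        raise ValueError(f"n_hvg={p.n_hvg} exceeds the {n_genes} genes available")
    V = np.expm1(nm.dense())  # back to the depth-normalized count scale
    mu = V.mean(axis=1)
    var = V.var(axis=1, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    ok = (var > 0) & (mu > 0)
    std_var = np.zeros(n_genes)
    if ok.sum() >= 3:
        lx, ly = np.log10(mu[ok]), np.log10(var[ok])
        # robust trend: unit slope (Poisson-consistent on this scale) with a
        # median intercept, tightened by trimming the high-residual tail so
        # variable genes do not drag their own trend upward
        resid = ly - lx
        trimmed = resid[resid <= np.quantile(resid, 0.8)]
        intercept = np.median(trimmed if trimmed.size >= 3 else resid)
        expected = np.full(n_genes, np.nan)
        expected[ok] = 10.0 ** (lx + intercept)
        clip = p.clip if p.clip is not None else np.sqrt(n_cells)
        for i in np.flatnonzero(ok):
            z = (V[i] - mu[i]) / np.sqrt(expected[i])
            z = np.clip(z, -clip, clip)
            std_var[i] = z.var(ddof=1)
    else:
        std_var[ok] = var[ok]
    order = sorted(range(n_genes), key=lambda i: (-std_var[i], str(nm.gene_ids[i])))
    return [str(nm.gene_ids[i]) for i in order[: p.n_hvg]]


def embed_pca(nm: NormalizedMatrix, genes: list[str] | None = None,
              n_dims: int = 30) -> Embedding:
    """PCA on per-gene centered, unit-scaled normalized values.

    Component signs are fixed by making each component's largest-magnitude
    gene loading positive, so repeated runs agree exactly.
    """
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    if genes is None:
        rows = np.arange(len(nm.gene_ids))
    else:
        missing = [g for g in genes if g not in gene_index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = np.array([gene_index[g] for g in genes])
    V = nm.dense()[rows]  # genes x cells
    n_genes, n_cells = V.shape
    if n_dims >= min(n_genes, n_cells):
        raise ValueError(f"n_dims={n_dims} must be < min(n_genes, n_cells)={min(n_genes, n_cells)}")
    mu = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = ((V - mu) / sd).T  # cells x genes
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    U, S, Vt = U[:, :n_dims], S[:n_dims], Vt[:n_dims]
    # deterministic sign: largest-|loading| positive per component
    for i in range(n_dims):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    coords = U * S
    total_var = (Z ** 2).sum()
    evr = (S ** 2) / total_var if total_var > 0 else np.zeros(n_dims)
    return Embedding(coords, nm.barcodes, explained_variance_ratio=evr)


def snn_graph(coords: np.ndarray, k: int = 20, prune: float = 1 / 15) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    The k-neighborhood of each cell includes the cell itself; edge weight
    between two cells is the Jaccard index of their neighborhoods, pruned
    below ``prune``.
    """
    n = coords.shape[0]
    k = min(k, n)
    nn = NearestNeighbors(n_neighbors=min(k - 1, n - 1)).fit(coords)
    idx = nn.kneighbors(return_distance=False)  # excludes self
    idx = np.column_stack([np.arange(n), idx[:, : k - 1]])
    rows = np.repeat(np.arange(n), idx.shape[1])
    A = sp.csr_matrix((np.ones(rows.size), (rows, idx.ravel())), shape=(n, n))
    shared = (A @ A.T).tocoo()
    denom = 2 * idx.shape[1] - shared.data
    w = shared.data / denom
    keep = (w >= prune) & (shared.row != shared.col)
    return sp.csr_matrix((w[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))


def cluster_cells(e: Embedding, resolution: float = 0.6, seed: int = 0,
                  k: int = 20) -> ClusterLabels:
    """Seeded modularity clustering of the SNN-Jaccard graph.

    Cluster ids are contiguous from 0, ordered by decreasing size (ties by
    smallest member index), so identical input and seed give identical labels.
    """
    import igraph as ig
    import leidenalg

    n = e.coordinates.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if n < k:
        warnings.warn(f"only {n} cells; reducing k from {k} to {n}")
        k = n
    W = sp.triu(snn_graph(e.coordinates, k=k), k=1).tocoo()
    g = ig.Graph(n=n, edges=list(zip(W.row.tolist(), W.col.tolist())),
                 edge_attrs={"weight": W.data.tolist()})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
    )
    raw = np.asarray(part.membership)
    order = sorted(np.unique(raw),
                   key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    return ClusterLabels(labels, e.barcodes, resolution, seed)
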