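"""Module scores, motif-score correlation, and upstream regulator ranking.

The integration mirrors the multi-omic regulator-inference step: module
scores of marker gene sets are computed on gene-activity matrices
(control-gene-corrected, Tirosh-style bins), optionally kNN-smoothed on an
embedding, then Pearson-correlated per cell against every motif deviation
z-score; modules are grouped by their correlation profiles and motifs ranked
per module to nominate candidate transcription factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from scipy.spatial.distance import squareform
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ModuleScoreMatrix",
    "module_score",
    "module_scores",
    "smooth_scores",
    "module_motif_correlation",
    "group_modules",
    "rank_regulators",
]


@dataclass
class ModuleScoreMatrix:
    scores: pd.DataFrame  # modules x cells
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0
    gene_sets: dict = field(default_factory=dict, repr=False)


def _bin_genes(means: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-size rank bins of genes by mean value (deterministic)."""
    order = np.argsort(means, kind="stable")
    bins = np.empty(len(means), dtype=int)
    for b, chunk in enumerate(np.array_split(order, min(n_bins, len(means)))):
        bins[chunk] = b
    return bins


def module_score(values, gene_ids, gene_set, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> np.ndarray:
    """Per-cell module score of one gene set.

    Genes are binned by mean value across cells; each target gene draws
    ``n_ctrl`` control genes with replacement from its bin (targets
    excluded). The score is the mean over targets of the target value minus
    the mean of its controls. Target genes absent from the matrix are dropped
    with a warning; a fully absent set is an error.
    """
    V = np.asarray(values.todense() if sp.issparse(values) else values, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    index = {g: i for i, g in enumerate(gene_ids)}
    targets = [g for g in sorted(set(gene_set)) if g in index]
    missing = sorted(set(gene_set) - set(targets))
    if not targets:
        raise ValueError("gene set entirely absent from the matrix")
    if missing:
        warnings.warn(f"{len(missing)} module genes absent from the matrix")
    tidx = np.array([index[g] for g in targets])
    means = V.mean(axis=1)
    bins = _bin_genes(means, n_bins)
    target_mask = np.zeros(len(gene_ids), dtype=bool)
    target_mask[tidx] = True
    rng = np.random.default_rng(seed)
    ctrl_sum = np.zeros(V.shape[1])
    warned = False
    for gi in tidx:
        pool = np.flatnonzero((bins == bins[gi]) & ~target_mask)
        if len(pool) == 0:
            if not warned:
                warnings.warn("a bin holds only target genes; controls drawn "
                              "from all non-target genes for those targets")
                warned = True
            pool = np.flatnonzero(~target_mask)
        if len(pool) == 0:
            raise ValueError("no control genes available")
        draws = rng.choice(pool, size=n_ctrl, replace=True)
        ctrl_sum += V[draws].mean(axis=0)
    return V[tidx].mean(axis=0) - ctrl_sum / len(tidx)


def module_scores(values, gene_ids, barcodes, gene_sets: dict,
                  n_bins: int = 24, n_ctrl: int = 100,
                  seed: int = 0) -> ModuleScoreMatrix:
    """Module x cell score matrix over a dict of gene sets."""
    rows = {str(name): module_score(values, gene_ids, genes, n_bins=n_bins,
                                    n_ctrl=n_ctrl, seed=seed)
            for name, genes in gene_sets.items()}
    df = pd.DataFrame(rows, index=np.asarray(barcodes, dtype=object)).T
    return ModuleScoreMatrix(df, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed,
                             gene_sets=dict(gene_sets))


def smooth_scores(values: np.ndarray, embedding, k: int = 15) -> np.ndarray:
    """Replace each cell's values by the mean over its k nearest embedding
    neighbors (the cell itself included); k=1 is the identity."""
    V = np.asarray(values, dtype=float)
    coords = embedding.coordinates
    n_cells = coords.shape[0]
    if V.shape[-1] != n_cells:
        raise ValueError("values and embedding disagree on cell count")
    if not (1 <= k <= n_cells):
        raise ValueError(f"k must lie in [1, {n_cells}]")
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    idx = nn.kneighbors(coords, return_distance=False)
    return V[..., idx].mean(axis=-1)


def module_motif_correlation(ms: ModuleScoreMatrix, dz) -> pd.DataFrame:
    """Pearson r between every module score and every motif deviation z-score.

    Cells are aligned by barcode; constant vectors yield missing entries.
    """
    zdf = pd.DataFrame(dz.z, index=dz.motif_ids, columns=dz.barcodes)
    shared = [b for b in ms.scores.columns if b in set(zdf.columns)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared cells")
    A = ms.scores[shared].to_numpy(dtype=float)   # modules x cells
    B = zdf[shared].to_numpy(dtype=float)         # motifs x cells
    valid_b = ~np.isnan(B).any(axis=1)

    def _std(M):
        Mc = M - M.mean(axis=1, keepdims=True)
        sd = Mc.std(axis=1)
        ok = sd > 0
        Mc[ok] /= sd[ok][:, None]
        return Mc, ok

    Ac, ok_a = _std(A.copy())
    Bn = np.where(np.isnan(B), 0.0, B)
    Bc, ok_b = _std(Bn)
    R = (Ac @ Bc.T) / len(shared)
    R[~ok_a, :] = np.nan
    R[:, ~(ok_b & valid_b)] = np.nan
    return pd.DataFrame(np.clip(R, -1, 1), index=ms.scores.index, columns=dz.motif_ids)


def group_modules(mmc: pd.DataFrame, n_groups: int = 4) -> pd.Series:
    """Average-linkage clustering of module rows on correlation distance.

    Missing correlations are imputed as 0 (with a warning) before clustering.
    Group ids are contiguous from 0 in order of first occurrence.
    """
    if n_groups > len(mmc):
        raise ValueError("n_groups exceeds the number of modules")
    M = mmc.to_numpy(dtype=float)
    if np.isnan(M).any():
        warnings.warn("missing correlations imputed as 0 for grouping")
        M = np.nan_to_num(M)
    n = M.shape[0]
    if n_groups == n:
        raw = np.arange(n)
    else:
        prof = M - M.mean(axis=1, keepdims=True)
        sd = prof.std(axis=1)
        sd[sd == 0] = 1.0
        corr = np.clip((prof / sd[:, None]) @ (prof / sd[:, None]).T / M.shape[1], -1, 1)
        D = 1 - corr
        np.fill_diagonal(D, 0.0)
        Z = sch.linkage(squareform(D, checks=False), method="average")
        raw = sch.fcluster(Z, t=n_groups, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = [remap.setdefault(c, len(remap)) for c in raw]
    return pd.Series(labels, index=mmc.index, name="group")


def rank_regulators(row: pd.Series, top_n: int | None = None) -> pd.Series:
    """Motifs ordered by descending correlation (ties by motif id).

    Missing entries are excluded; an all-missing row is an error.
    """
    clean = row.dropna()
    if clean.empty:
        raise ValueError("no non-missing correlations for this module")
    order = sorted(clean.index, key=lambda m: (-clean[m], str(m)))
    ranked = clean.loc[order]
    return ranked.iloc[:top_n] if top_n is not None else ranked
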