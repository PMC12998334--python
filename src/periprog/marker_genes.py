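"""Per-cluster marker genes: Wilcoxon rank-sum one-vs-rest differential
expression and the cluster-specific-gene rule (log2FC > 1, adjusted P < 0.01).

The fold change is log2((mean_in + 1) / (mean_out + 1)) over back-transformed
normalized expression (expm1 of the log-normalized values), pinned by the
worked example in the tests. Only positive fold changes above the prefilter
are tested; Benjamini-Hochberg adjustment runs over all tests actually
performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import adjust_pvalues, mann_whitney
from .sc_preprocess import ClusterLabels, NormalizedMatrix

__all__ = ["DEGParams", "find_markers", "select_cluster_specific"]


@dataclass
class DEGParams:
    prefilter_logfc: float = 0.25
    only_positive: bool = True
    sig_log2fc: float = 1.0
    sig_alpha: float = 0.01
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sig_log2fc >= self.prefilter_logfc >= 0):
            raise ValueError("need sig_log2fc >= prefilter_logfc >= 0")


def find_markers(nm: NormalizedMatrix, labels: ClusterLabels,
                 p: DEGParams | None = None) -> pd.DataFrame:
    """One-vs-rest marker table for every cluster with >= 3 cells.

    Columns: cluster, gene, log2fc, p, p_adj, frac_in, frac_out.
    """
    p = p or DEGParams()
    if not np.array_equal(nm.barcodes, labels.barcodes):
        raise ValueError("matrix and labels must cover the same barcodes in order")
    V = nm.dense()  # genes x cells
    E = np.expm1(V)
    clusters = np.unique(labels.labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    rows = []
    for c in clusters:
        mask = labels.labels == c
        n_in = int(mask.sum())
        if n_in < 3:
            warnings.warn(f"cluster {c} has {n_in} cells; skipped")
            continue
        mean_in = E[:, mask].mean(axis=1)
        mean_out = E[:, ~mask].mean(axis=1)
        log2fc = np.log2((mean_in + p.pseudocount) / (mean_out + p.pseudocount))
        frac_in = (V[:, mask] > 0).mean(axis=1)
        frac_out = (V[:, ~mask] > 0).mean(axis=1)
        cand = log2fc > p.prefilter_logfc if p.only_positive else np.abs(log2fc) > p.prefilter_logfc
        mode = "exact" if max(n_in, V.shape[1] - n_in) <= 25 else "auto"
        for gi in np.flatnonzero(cand):
            pv = mann_whitney(V[gi, mask], V[gi, ~mask], mode=mode).p
            rows.append((int(c), str(nm.gene_ids[gi]), float(log2fc[gi]), pv,
                         float(frac_in[gi]), float(frac_out[gi])))
    mt = pd.DataFrame(rows, columns=["cluster", "gene", "log2fc", "p", "frac_in", "frac_out"])
    mt["p_adj"] = adjust_pvalues(mt["p"].to_numpy(), method="bh") if len(mt) else []
    return mt[["cluster", "gene", "log2fc", "p", "p_adj", "frac_in", "frac_out"]]


def select_cluster_specific(mt: pd.DataFrame,
                            p: DEGParams | None = None) -> dict[int, list[str]]:
    """Cluster-specific genes: strictly log2fc > sig_log2fc and p_adj < sig_alpha."""
    p = p or DEGParams()
    hits = mt[(mt["log2fc"] > p.sig_log2fc) & (mt["p_adj"] < p.sig_alpha)]
    out: dict[int, list[str]] = {}
    for c, grp in hits.groupby("cluster"):
        out[int(c)] = sorted(grp["gene"].tolist())
    return out
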