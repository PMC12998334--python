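"""Per-sample consensus NMF and cross-sample recurrent-program consolidation.

The pipeline mirrors the standard single-cell program-discovery recipe:

1. factorize each sample's HVG-restricted nonnegative expression matrix by
   multiplicative-update NMF over several seeded restarts,
2. pool L2-normalized spectra, drop density outliers, group the survivors by
   k-means and take per-gene medians as consensus spectra (usages refit by
   nonnegative least squares),
3. select the rank k in a candidate range by the stability (mean silhouette,
   cosine distance) of the pooled-component grouping,
4. keep each program's top-n genes by weight as its signature,
5. consolidate signatures across samples by Jaccard similarity and
   average-linkage hierarchical clustering into recurrent programs (RPs),
6. call a gene an RP gene when it occurs in at least ``min_frac`` (default
   one-third, boundary inclusive) of the RP's member signatures,
7. test RP gene sets against reference program gene sets with the
   hypergeometric upper tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats as _st
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .cohort_stats import adjust_pvalues

__all__ = [
    "ProgramSpectra",
    "ProgramUsage",
    "GeneSignature",
    "RecurrentProgram",
    "OverlapResult",
    "RankSelection",
    "nmf_factorize",
    "consensus_nmf",
    "select_rank",
    "top_genes",
    "jaccard_matrix",
    "cluster_programs",
    "consensus_from_pool",
    "define_rp_genes",
    "consolidate_programs",
    "overlap_test",
    "overlap_tests",
    "score_rp_activity",
    "nmf_input",
]

_EPS = 1e-12


@dataclass
class ProgramSpectra:
    weights: np.ndarray  # programs x genes, nonnegative
    gene_ids: np.ndarray
    sample_id: str = "sample"
    k: int = 0
    error_history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.weights.min(initial=0) < 0:
            raise ValueError("spectra must be nonnegative")
        if np.any(self.weights.sum(axis=1) == 0):
            raise ValueError("all-zero program row")
        self.k = self.k or self.weights.shape[0]


@dataclass
class ProgramUsage:
    weights: np.ndarray  # cells x programs, nonnegative
    barcodes: np.ndarray | None = None


@dataclass
class GeneSignature:
    program_id: str
    sample_id: str
    genes: list[str]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")


@dataclass
class RecurrentProgram:
    rp_id: int
    members: list[tuple[str, str]]  # (sample_id, program_id)
    rp_genes: set[str]
    min_frac: float = 1 / 3


@dataclass
class OverlapResult:
    intersection: int
    size_a: int
    size_b: int
    universe: int
    p: float
    odds_ratio: float


@dataclass
class RankSelection:
    k_range: list[int]
    stability: dict[int, float]
    error: dict[int, float]
    chosen_k: int


def nmf_input(values: np.ndarray, scale: bool = True) -> np.ndarray:
    """HVG-restricted normalized values, per-gene unit-variance scaled.

    Dividing each gene row by its standard deviation keeps nonnegativity
    (no centering); zero-variance rows are left unscaled.
    """
    V = np.asarray(values, dtype=float)
    if V.min(initial=0) < 0:
        raise ValueError("expected a nonnegative matrix")
    if not scale:
        return V
    sd = V.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return V / sd


def nmf_factorize(matrix: np.ndarray, k: int, seed: int = 0,
                  max_iter: int = 500, tol: float = 1e-6,
                  gene_ids: np.ndarray | None = None,
                  sample_id: str = "sample") -> tuple[ProgramSpectra, ProgramUsage]:
    """Multiplicative-update NMF of a nonnegative gene x cell matrix.

    Minimizes squared Frobenius error from a seeded random nonnegative
    initialization; the relative error sequence is recorded and is
    non-increasing. Stops when the relative error change falls below ``tol``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.min(initial=0) < 0:
        raise ValueError("NMF requires a nonnegative matrix")
    m, n = X.shape
    if not (0 < k < min(m, n)):
        raise ValueError(f"k={k} must satisfy 0 < k < min{X.shape}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    W = rng.uniform(_EPS, 1.0, size=(m, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, n)) * scale
    norm_x = np.linalg.norm(X)
    errors: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        err = np.linalg.norm(X - W @ H) / max(norm_x, _EPS)
        errors.append(err)
        if prev - err < tol * max(prev, _EPS):
            break
        prev = err
    # guard against numerically dead components
    dead = W.sum(axis=0) < _EPS
    if dead.any():
        W[:, dead] = _EPS
    gene_ids = gene_ids if gene_ids is not None else np.array([f"g{i}" for i in range(m)], dtype=object)
    spectra = ProgramSpectra(W.T, gene_ids, sample_id=sample_id, k=k, error_history=errors)
    return spectra, ProgramUsage(H.T)


def _l2_normalize_rows(A: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return A / norms


def _pool_spectra(matrix, k, seeds, max_iter, tol, gene_ids, sample_id):
    pooled = []
    for s in seeds:
        spec, _ = nmf_factorize(matrix, k, seed=s, max_iter=max_iter, tol=tol,
                                gene_ids=gene_ids, sample_id=sample_id)
        pooled.append(_l2_normalize_rows(spec.weights))
    return np.vstack(pooled)


def consensus_nmf(matrix: np.ndarray, k: int, n_restarts: int = 10,
                  density_threshold: float = 0.5, seed: int = 0,
                  seeds: list[int] | None = None, max_iter: int = 500,
                  tol: float = 1e-6, gene_ids: np.ndarray | None = None,
                  sample_id: str = "sample") -> tuple[ProgramSpectra, ProgramUsage]:
    """Consensus NMF: restart pooling, density filtering, k-means grouping,
    median consensus spectra, NNLS usage refit.

    Components whose mean cosine distance to their floor(n_restarts/2)
    nearest pooled neighbors exceeds ``density_threshold`` are discarded as
    local-optimum outliers before grouping.
    """
    if seeds is None:
        if n_restarts < 2:
            raise ValueError("n_restarts must be >= 2")
        seeds = [seed + i for i in range(n_restarts)]
    n_restarts = len(seeds)
    X = np.asarray(matrix, dtype=float)
    gene_ids = gene_ids if gene_ids is not None else np.array(
        [f"g{i}" for i in range(X.shape[0])], dtype=object)
    pooled = _pool_spectra(X, k, seeds, max_iter, tol, gene_ids, sample_id)
    consensus = consensus_from_pool(pooled, k, n_restarts, density_threshold, seed)
    usage = refit_usage(X, consensus)
    spectra = ProgramSpectra(consensus, gene_ids, sample_id=sample_id, k=k)
    return spectra, ProgramUsage(usage)


def consensus_from_pool(pooled: np.ndarray, k: int, n_restarts: int,
                        density_threshold: float = 0.5, seed: int = 0) -> np.ndarray:
    """Density-filter pooled L2-normalized spectra and collapse them into k
    consensus spectra (k-means grouping, per-gene medians, L2 renormalized,
    deterministic program order)."""
    pooled = _l2_normalize_rows(np.asarray(pooled, dtype=float))
    sim = np.clip(pooled @ pooled.T, -1, 1)
    dist = 1 - sim
    np.fill_diagonal(dist, np.inf)
    n_near = max(1, n_restarts // 2)
    near = np.sort(dist, axis=1)[:, :n_near]
    keep = near.mean(axis=1) <= density_threshold
    if keep.sum() < k:
        raise ValueError("density filtering removed too many components; "
                         "raise density_threshold")
    survivors = pooled[keep]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(survivors)
    consensus = np.zeros((k, pooled.shape[1]))
    for g in range(k):
        members = survivors[km.labels_ == g]
        if members.shape[0] == 0:
            raise ValueError("a consensus group lost all components; "
                             "raise density_threshold")
        consensus[g] = np.median(members, axis=0)
    consensus = np.maximum(consensus, 0)
    if np.any(consensus.sum(axis=1) == 0):
        raise ValueError("empty consensus spectrum; raise density_threshold")
    consensus = _l2_normalize_rows(consensus)
    # deterministic program order: by descending peak weight, then peak gene
    order = np.lexsort((np.argmax(consensus, axis=1), -consensus.max(axis=1)))
    return consensus[order]


def refit_usage(X: np.ndarray, spectra: np.ndarray) -> np.ndarray:
    """Nonnegative least-squares usage of each cell against fixed spectra."""
    W = spectra.T  # genes x k
    n_cells = X.shape[1]
    H = np.zeros((n_cells, spectra.shape[0]))
    for c in range(n_cells):
        H[c], _ = nnls(W, X[:, c])
    return H


def select_rank(matrix: np.ndarray, k_range=range(4, 10), n_restarts: int = 10,
                seed: int = 0, max_iter: int = 300, tol: float = 1e-5,
                gene_ids: np.ndarray | None = None,
                sample_id: str = "sample") -> RankSelection:
    """Pick the factorization rank by restart stability.

    For each candidate k the pooled, L2-normalized restart spectra are
    partitioned into k groups by seeded k-means; stability is the mean cosine
    silhouette of that partition and the reconstruction error is the relative
    Frobenius error of the consensus fit. The chosen k maximizes
    stability - error (ties to the smaller k): under-factorization is often
    perfectly stable, so the fit term supplies the information a human
    inspecting both curves would use.
    """
    k_range = sorted(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    X = np.asarray(matrix, dtype=float)
    gene_ids = gene_ids if gene_ids is not None else np.array(
        [f"g{i}" for i in range(X.shape[0])], dtype=object)
    stability: dict[int, float] = {}
    error: dict[int, float] = {}
    norm_x = np.linalg.norm(X)
    for k in k_range:
        seeds = [seed + i for i in range(n_restarts)]
        pooled = _pool_spectra(X, k, seeds, max_iter, tol, gene_ids, sample_id)
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pooled)
        if len(np.unique(km.labels_)) < 2:
            stability[k] = 0.0
        else:
            stability[k] = float(silhouette_score(pooled, km.labels_, metric="cosine"))
        consensus = np.zeros((k, X.shape[0]))
        for g in range(k):
            members = pooled[km.labels_ == g]
            consensus[g] = np.median(members, axis=0) if len(members) else 0.0
        consensus = np.maximum(consensus, _EPS)
        usage = refit_usage(X, consensus)
        error[k] = float(np.linalg.norm(X - consensus.T @ usage.T) / max(norm_x, _EPS))
    chosen = k_range[0]
    for k in k_range[1:]:
        if stability[k] - error[k] > stability[chosen] - error[chosen]:
            chosen = k
    return RankSelection(list(k_range), stability, error, chosen)


def top_genes(s: ProgramSpectra, n_top: int = 200) -> list[GeneSignature]:
    """Top-``n_top`` genes of each program by descending weight, ties by id."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    out = []
    for pi, row in enumerate(s.weights):
        order = sorted(range(len(row)), key=lambda i: (-row[i], str(s.gene_ids[i])))
        genes = [str(s.gene_ids[i]) for i in order[:n_top]]
        out.append(GeneSignature(program_id=f"{s.sample_id}_p{pi}",
                                 sample_id=s.sample_id, genes=genes))
    return out


def jaccard_matrix(signatures: list[GeneSignature]) -> pd.DataFrame:
    """Pairwise Jaccard index |A∩B|/|A∪B| of signature gene sets."""
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    sets = []
    for s in signatures:
        if not s.genes:
            raise ValueError(f"signature {s.program_id} is empty")
        sets.append(set(s.genes))
    n = len(sets)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            J[i, j] = J[j, i] = inter / union
    ids = [s.program_id for s in signatures]
    return pd.DataFrame(J, index=ids, columns=ids)


def cluster_programs(jaccard: pd.DataFrame, n_rp: int) -> np.ndarray:
    """Average-linkage hierarchical clustering of programs on 1 - Jaccard.

    Returns one integer RP label per program, contiguous from 0 in order of
    first occurrence; deterministic given input order.
    """
    J = np.asarray(jaccard, dtype=float)
    n = J.shape[0]
    if n_rp > n:
        raise ValueError("n_rp exceeds the number of programs")
    if n_rp == n:
        return np.arange(n)
    D = 1.0 - J
    np.fill_diagonal(D, 0.0)
    Z = sch.linkage(squareform(D, checks=False), method="average")
    raw = sch.fcluster(Z, t=n_rp, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        labels[i] = remap.setdefault(c, len(remap))
    return labels


def define_rp_genes(signatures: list[GeneSignature], min_frac: float = 1 / 3) -> set[str]:
    """Genes present in at least ``min_frac`` of the member signatures.

    The boundary is inclusive: with three members, a gene in exactly one
    signature (1/3) is included.
    """
    if not signatures:
        raise ValueError("need at least one member signature")
    m = len(signatures)
    counts: dict[str, int] = {}
    for s in signatures:
        for g in s.genes:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_frac * m - 1e-9}


def consolidate_programs(signatures: list[GeneSignature], n_rp: int,
                         min_frac: float = 1 / 3) -> list[RecurrentProgram]:
    """Full consolidation: Jaccard matrix, tree cut, RP gene definition."""
    J = jaccard_matrix(signatures)
    labels = cluster_programs(J, n_rp)
    rps = []
    for rp in range(labels.max() + 1):
        members = [signatures[i] for i in np.flatnonzero(labels == rp)]
        rps.append(RecurrentProgram(
            rp_id=rp,
            members=[(s.sample_id, s.program_id) for s in members],
            rp_genes=define_rp_genes(members, min_frac),
            min_frac=min_frac,
        ))
    return rps


def overlap_test(set_a: set[str], set_b: set[str], universe: int) -> OverlapResult:
    """Hypergeometric upper-tail significance of the overlap of two gene sets."""
    a, b = set(set_a), set(set_b)
    if universe < len(a | b):
        raise ValueError("universe smaller than the union of the sets")
    i = len(a & b)
    na, nb = len(a), len(b)
    p = float(_st.hypergeom.sf(i - 1, universe, na, nb))
    d11, d12, d21 = i, na - i, nb - i
    d22 = universe - na - nb + i
    odds = (d11 * d22) / (d12 * d21) if d12 * d21 > 0 else (np.inf if d11 * d22 > 0 else np.nan)
    return OverlapResult(i, na, nb, universe, min(p, 1.0), odds)


def overlap_tests(rp_sets: dict[str, set[str]], reference_sets: dict[str, set[str]],
                  universe: int) -> pd.DataFrame:
    """All RP x reference overlap tests with BH adjustment across the batch."""
    rows = []
    for rp_id, a in rp_sets.items():
        for ref_id, b in reference_sets.items():
            r = overlap_test(a, b, universe)
            rows.append((rp_id, ref_id, r.intersection, r.size_a, r.size_b,
                         r.universe, r.p, r.odds_ratio))
    df = pd.DataFrame(rows, columns=["rp", "reference", "intersection", "size_rp",
                                     "size_ref", "universe", "p", "odds_ratio"])
    df["p_adj"] = adjust_pvalues(df["p"].to_numpy(), method="bh") if len(df) else []
    return df


def score_rp_activity(nm, rp_genes: dict[str, set[str]] | dict[int, set[str]],
                      seed: int = 0, n_bins: int = 24, n_ctrl: int = 100) -> pd.DataFrame:
    """RP x cell module-score matrix (control-gene-corrected mean expression)."""
    from .regulator_integration import module_score

    V = nm.dense()
    rows = {}
    for rp_id, genes in rp_genes.items():
        rows[str(rp_id)] = module_score(V, nm.gene_ids, genes, n_bins=n_bins,
                                        n_ctrl=n_ctrl, seed=seed)
    return pd.DataFrame(rows, index=nm.barcodes).T
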