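"""scATAC fragment QC, peak x cell counting, LSI embedding, gene activity
scores and chromVAR-style motif deviation z-scores.

Coordinate conventions: fragments and peaks are 0-based half-open. A fragment
contributes Tn5 insertions at ``start`` and ``end - 1`` (fragment files are
assumed already Tn5-shifted), each weighted by the duplicate count, so a
fragment falling entirely inside one peak adds 2 to that peak's cell count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "FragmentSet",
    "AtacQCParams",
    "PeakSet",
    "PeakMatrix",
    "MotifAnnotationMatrix",
    "BackgroundPeaks",
    "DeviationMatrix",
    "GeneActivityMatrix",
    "tss_enrichment",
    "fragment_qc",
    "peak_cell_matrix",
    "embed_lsi",
    "gene_activity",
    "background_peaks",
    "motif_deviations",
]


@dataclass
class FragmentSet:
    """Columnar fragment records (chrom, start, end, barcode, duplicate count)."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    barcode: np.ndarray
    count: np.ndarray
    genome: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.barcode = np.asarray(self.barcode, dtype=object)
        self.count = np.asarray(self.count, dtype=np.int64)
        n = len(self.chrom)
        if not all(len(a) == n for a in (self.start, self.end, self.barcode, self.count)):
            raise ValueError("fragment columns must have equal length")
        if np.any(self.start < 0) or np.any(self.end <= self.start):
            raise ValueError("fragments need 0 <= start < end")
        if np.any(self.count < 1):
            raise ValueError("duplicate counts must be >= 1")
        for c, length in self.genome.items():
            sel = self.chrom == c
            if sel.any() and self.end[sel].max() > length:
                raise ValueError(f"fragment beyond end of {c}")

    def __len__(self) -> int:
        return len(self.chrom)

    def insertions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(chrom, position, barcode, weight) of all Tn5 insertion sites."""
        chrom = np.concatenate([self.chrom, self.chrom])
        pos = np.concatenate([self.start, self.end - 1])
        bc = np.concatenate([self.barcode, self.barcode])
        w = np.concatenate([self.count, self.count])
        return chrom, pos, bc, w


@dataclass
class AtacQCParams:
    min_tss_enrichment: float = 4.0
    min_unique_fragments: int = 1500
    tss_window: int = 50          # +/- bp around the TSS
    flank_lo: int = 1901          # flank window bp from the TSS
    flank_hi: int = 2000
    flank_floor: float = 0.1      # pseudo-count floor on flank insertions
    max_score: float = 100.0

    def __post_init__(self) -> None:
        if min(self.min_tss_enrichment, self.min_unique_fragments,
               self.tss_window, self.flank_lo, self.flank_hi) <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class PeakSet:
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc_content: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.gc_content = np.asarray(self.gc_content, dtype=float)
        if np.any((self.gc_content < 0) | (self.gc_content > 1)):
            raise ValueError("GC content must lie in [0, 1]")
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            s, e = self.start[sel], self.end[sel]
            order = np.argsort(s)
            if np.any(e[order][:-1] > s[order][1:]):
                raise ValueError(f"overlapping peaks on {c}; merge before counting")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def ids(self) -> np.ndarray:
        return np.array([f"{c}:{s}-{e}" for c, s, e in
                         zip(self.chrom, self.start, self.end)], dtype=object)


@dataclass
class PeakMatrix:
    counts: sp.csr_matrix  # peaks x cells
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.counts.shape[1] != len(self.barcodes):
            raise ValueError("column count must equal number of barcodes")


@dataclass
class MotifAnnotationMatrix:
    membership: sp.csr_matrix  # peaks x motifs, boolean
    motif_ids: np.ndarray

    def __post_init__(self) -> None:
        self.membership = sp.csr_matrix(self.membership).astype(bool)
        self.motif_ids = np.asarray(self.motif_ids, dtype=object)
        if self.membership.shape[1] != len(self.motif_ids):
            raise ValueError("motif id count mismatch")


@dataclass
class BackgroundPeaks:
    indices: np.ndarray  # peaks x n_bg

    @property
    def n_bg(self) -> int:
        return self.indices.shape[1]


@dataclass
class DeviationMatrix:
    raw: np.ndarray  # motifs x cells
    z: np.ndarray
    motif_ids: np.ndarray
    barcodes: np.ndarray
    n_bg: int


@dataclass
class GeneActivityMatrix:
    scores: np.ndarray  # genes x cells
    gene_ids: np.ndarray
    barcodes: np.ndarray


def _insertion_tss_distance(frag: FragmentSet, tss_positions: dict[str, np.ndarray]):
    """Distance of every insertion to its nearest TSS (inf off-chromosome)."""
    chrom, pos, bc, w = frag.insertions()
    dist = np.full(len(pos), np.inf)
    for c, sites in tss_positions.items():
        sites = np.sort(np.asarray(sites, dtype=np.int64))
        sel = chrom == c
        if not sel.any() or len(sites) == 0:
            continue
        p = pos[sel]
        right = np.searchsorted(sites, p)
        d_right = np.where(right < len(sites), np.abs(sites[np.minimum(right, len(sites) - 1)] - p), np.inf)
        d_left = np.where(right > 0, np.abs(p - sites[np.maximum(right - 1, 0)]), np.inf)
        dist[sel] = np.minimum(d_left, d_right)
    return bc, w, dist


def tss_enrichment(frag: FragmentSet, tss_positions: dict[str, np.ndarray],
                   q: AtacQCParams | None = None) -> pd.Series:
    """Per-barcode TSS enrichment: insertion density within +/-``tss_window``
    of the nearest TSS over the density in the distal flank windows.

    The flank insertion count is floored at ``flank_floor`` so barcodes with
    all insertions at TSSs get the capped maximum rather than a division by
    zero; barcodes with no insertions in either window score 0.
    """
    q = q or AtacQCParams()
    n_tss = sum(len(v) for v in tss_positions.values())
    if n_tss == 0:
        raise ValueError("need at least one TSS")
    bc, w, dist = _insertion_tss_distance(frag, tss_positions)
    codes, uniq = pd.factorize(bc)
    in_tss = dist <= q.tss_window
    in_flank = (dist >= q.flank_lo) & (dist <= q.flank_hi)
    tss_counts = np.bincount(codes[in_tss], weights=w[in_tss], minlength=len(uniq))
    flank_counts = np.bincount(codes[in_flank], weights=w[in_flank], minlength=len(uniq))
    tss_bp = 2 * q.tss_window + 1
    flank_bp = 2 * (q.flank_hi - q.flank_lo + 1)
    dens_tss = tss_counts / tss_bp
    dens_flank = np.maximum(flank_counts, q.flank_floor) / flank_bp
    score = np.minimum(dens_tss / dens_flank, q.max_score)
    score[(tss_counts == 0) & (flank_counts == 0)] = 0.0
    return pd.Series(score, index=uniq, name="tss_enrichment")


def unique_fragment_counts(frag: FragmentSet) -> pd.Series:
    """Distinct (chrom, start, end) fragments per barcode."""
    df = pd.DataFrame({"barcode": frag.barcode, "chrom": frag.chrom,
                       "start": frag.start, "end": frag.end})
    return df.drop_duplicates().groupby("barcode", sort=False).size()


def fragment_qc(frag: FragmentSet, scores: pd.Series,
                q: AtacQCParams | None = None) -> np.ndarray:
    """Barcodes passing TSS enrichment >= threshold and unique fragments >= floor."""
    q = q or AtacQCParams()
    uniq = unique_fragment_counts(frag)
    keep = []
    for bc, n in uniq.items():
        if n >= q.min_unique_fragments and scores.get(bc, 0.0) >= q.min_tss_enrichment:
            keep.append(bc)
    return np.array(keep, dtype=object)


def peak_cell_matrix(frag: FragmentSet, peaks: PeakSet,
                     barcodes: np.ndarray) -> PeakMatrix:
    """Count Tn5 insertions (start and end-1, times duplicate count) per peak
    and barcode. Peaks must be sorted and non-overlapping per chromosome
    (enforced by PeakSet)."""
    barcodes = np.asarray(barcodes, dtype=object)
    bc_index = {b: i for i, b in enumerate(barcodes)}
    chrom, pos, bc, w = frag.insertions()
    col = np.array([bc_index.get(b, -1) for b in bc])
    counts = np.zeros((len(peaks), len(barcodes)), dtype=np.int64)
    for c in np.unique(peaks.chrom):
        psel = peaks.chrom == c
        pidx = np.flatnonzero(psel)
        order = np.argsort(peaks.start[psel])
        starts = peaks.start[psel][order]
        ends = peaks.end[psel][order]
        pidx = pidx[order]
        fsel = (chrom == c) & (col >= 0)
        if not fsel.any():
            continue
        p = pos[fsel]
        slot = np.searchsorted(starts, p, side="right") - 1
        ok = (slot >= 0) & (p < ends[np.maximum(slot, 0)])
        rows = pidx[slot[ok]]
        np.add.at(counts, (rows, col[fsel][ok]), w[fsel][ok])
    return PeakMatrix(sp.csr_matrix(counts), barcodes)


def embed_lsi(pm: PeakMatrix, n_dims: int = 30, seed: int = 0,
              depth_corr_cutoff: float = 0.9):
    """Single-pass LSI: TF-IDF, log scaling, truncated SVD.

    The first component is dropped when its absolute correlation with log
    sequencing depth exceeds ``depth_corr_cutoff`` (otherwise the last
    computed component is dropped), so the result always has ``n_dims``
    dimensions. A zero-variance input is returned as an all-zero embedding
    with a warning.
    """
    from .sc_preprocess import Embedding

    C = pm.counts.astype(float)
    n_peaks, n_cells = C.shape
    if n_peaks <= n_dims + 1:
        raise ValueError("need more peaks than n_dims + 1")
    depth = np.asarray(C.sum(axis=0)).ravel()
    tf = C.multiply(1.0 / np.maximum(depth, 1e-12)[None, :])
    df = np.asarray((C > 0).sum(axis=1)).ravel()
    idf = np.log1p(n_cells / np.maximum(df, 1))
    mat = tf.multiply(idf[:, None]).tocsr()
    mat.data = np.log1p(mat.data * 1e4)
    if mat.nnz == 0 or np.allclose(mat.data, 0):
        warnings.warn("degenerate peak matrix: zero informative variance")
        return Embedding(np.zeros((n_cells, n_dims)), pm.barcodes)
    svd = TruncatedSVD(n_components=n_dims + 1, random_state=seed)
    coords = svd.fit_transform(mat.T)  # cells x (n_dims + 1)
    logd = np.log1p(depth)
    if np.std(coords[:, 0]) > 0 and np.std(logd) > 0:
        r = np.corrcoef(coords[:, 0], logd)[0, 1]
    else:
        r = 0.0
    keep = slice(1, n_dims + 1) if abs(r) > depth_corr_cutoff else slice(0, n_dims)
    return Embedding(coords[:, keep], pm.barcodes)


def gene_activity(frag: FragmentSet, gene_models: pd.DataFrame,
                  barcodes: np.ndarray, decay: float = 5000.0,
                  max_dist: float = 100_000.0, upstream: int = 2000,
                  scale_factor: float = 10_000.0) -> GeneActivityMatrix:
    """Accessibility-derived gene scores.

    ``gene_models`` columns: gene, chrom, strand, tss, end. Insertions inside
    the strand-oriented window [TSS - ``upstream``, gene end] weigh 1; beyond
    the window (either side, up to ``max_dist``) the weight decays as
    exp(-d / ``decay``). Scores are depth-normalized to ``scale_factor`` per
    cell and ln(1+x) transformed.
    """
    required = {"gene", "chrom", "strand", "tss", "end"}
    if not required <= set(gene_models.columns):
        raise ValueError(f"gene_models must have columns {sorted(required)}")
    barcodes = np.asarray(barcodes, dtype=object)
    bc_index = {b: i for i, b in enumerate(barcodes)}
    chrom_all, pos_all, bc_all, w_all = frag.insertions()
    col = np.array([bc_index.get(b, -1) for b in bc_all])
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c in np.unique(chrom_all):
        sel = (chrom_all == c) & (col >= 0)
        order = np.argsort(pos_all[sel], kind="stable")
        by_chrom[c] = (pos_all[sel][order], col[sel][order], w_all[sel][order])
    genes = gene_models["gene"].to_numpy()
    scores = np.zeros((len(genes), len(barcodes)))
    for gi, row in enumerate(gene_models.itertuples(index=False)):
        if row.strand == "+":
            lo, hi = row.tss - upstream, row.end
        elif row.strand == "-":
            lo, hi = row.end, row.tss + upstream
        else:
            raise ValueError(f"gene {row.gene!r}: bad strand {row.strand!r}")
        if hi <= lo:
            raise ValueError(f"gene {row.gene!r}: empty window [{lo}, {hi})")
        if row.chrom not in by_chrom:
            continue
        pos, cc, w = by_chrom[row.chrom]
        a = np.searchsorted(pos, lo - max_dist, side="left")
        b = np.searchsorted(pos, hi + max_dist, side="right")
        if a == b:
            continue
        p = pos[a:b]
        d = np.maximum.reduce([lo - p, p - hi, np.zeros(b - a)])
        weight = np.exp(-d / decay) * w[a:b]
        np.add.at(scores[gi], cc[a:b], weight)
    totals = scores.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(totals > 0, scores * (scale_factor / np.maximum(totals, 1e-300)), 0.0)
    return GeneActivityMatrix(np.log1p(scores), np.asarray(genes, dtype=object), barcodes)


def background_peaks(pm: PeakMatrix, peaks: PeakSet, n_bg: int = 50,
                     seed: int = 0, n_neighbors: int = 250) -> BackgroundPeaks:
    """GC- and accessibility-matched background draws for every peak.

    Each peak draws ``n_bg`` peaks with replacement (self allowed) from its
    ``n_neighbors`` nearest neighbors in standardized (GC, log1p mean
    accessibility) space; when fewer peaks exist the pool is all peaks.
    """
    n_peaks = pm.counts.shape[0]
    if len(peaks) != n_peaks:
        raise ValueError("peak set and peak matrix disagree on peak count")
    if n_bg > 0 and n_peaks == 0:
        raise ValueError("no peaks")
    mean_acc = np.log1p(np.asarray(pm.counts.mean(axis=1)).ravel())
    feats = np.column_stack([peaks.gc_content, mean_acc])
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / sd
    pool_size = min(n_neighbors, n_peaks)
    nn = NearestNeighbors(n_neighbors=pool_size).fit(feats)
    neigh = nn.kneighbors(feats, return_distance=False)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, pool_size, size=(n_peaks, n_bg))
    return BackgroundPeaks(indices=np.take_along_axis(neigh, draws, axis=1))


def _fractional_deviation(X: np.ndarray, frac: np.ndarray,
                          totals: np.ndarray) -> np.ndarray:
    E = np.outer(frac, totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = (X - E) / E
    dev[E == 0] = np.nan
    return dev


def motif_deviations(pm: PeakMatrix, ma: MotifAnnotationMatrix,
                     bg: BackgroundPeaks) -> DeviationMatrix:
    """chromVAR-style bias-corrected motif accessibility deviations.

    For motif m and cell c, raw = (X - E)/E where X is the cell's insertion
    count in the motif's peaks and E is the cell's total insertions times the
    all-cell fraction of insertions falling in those peaks. The z-score
    standardizes raw against the same statistic computed over each matched
    background peak draw.
    """
    C = pm.counts
    if ma.membership.shape[0] != C.shape[0]:
        raise ValueError("annotation peak count mismatch")
    if bg.indices.shape[0] != C.shape[0]:
        raise ValueError("background peak count mismatch")
    M = ma.membership.astype(float)
    totals = np.asarray(C.sum(axis=0)).ravel().astype(float)
    peak_sums = np.asarray(C.sum(axis=1)).ravel().astype(float)
    T = peak_sums.sum()
    if T == 0:
        raise ValueError("empty peak matrix")
    Cd = np.asarray(C.todense(), dtype=float)
    X = M.T @ Cd
    frac = (M.T @ peak_sums) / T
    raw = _fractional_deviation(X, frac, totals)
    if np.isnan(raw).any():
        warnings.warn("motifs with zero expected counts produce missing deviations")
    n_bg = bg.n_bg
    bgdevs = np.empty((n_bg,) + raw.shape)
    for j in range(n_bg):
        idx = bg.indices[:, j]
        Xj = M.T @ Cd[idx, :]
        fj = (M.T @ peak_sums[idx]) / T
        bgdevs[j] = _fractional_deviation(Xj, fj, totals)
    mean_bg = bgdevs.mean(axis=0)
    sd_bg = bgdevs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (raw - mean_bg) / sd_bg
    z[np.isclose(sd_bg, 0) & np.isclose(raw - mean_bg, 0)] = 0.0
    return DeviationMatrix(raw=raw, z=z, motif_ids=ma.motif_ids,
                           barcodes=pm.barcodes, n_bg=n_bg)
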