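"""Synthetic multi-sample RNA and paired ATAC data with planted ground truth.

The generator emulates the statistical structure of the real cohort so that
every downstream stage is testable without external downloads:

* ``make_program_cohort`` — one gene x cell count matrix per sample whose
  cells mix sample-shared and sample-private nonnegative expression programs
  under a Poisson observation model (cNMF / recurrent-program recovery).
* ``make_multiome_pair`` — an RNA matrix plus a paired ATAC arm (fragments,
  GC-annotated peaks, motif annotations) in which the peaks carrying one
  planted TF's motif gain accessibility in proportion to program-1 usage
  (chromVAR / regulator-inference recovery).
* ``make_fragments`` — fragment files with a controllable fraction of
  TSS-proximal insertions (TSS-enrichment QC).
* ``make_cohort_tables`` — the small printed cohort tables (the 2x2
  engraftment-metastasis table and the passage-interval groups).

Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .atac_scores import FragmentSet, MotifAnnotationMatrix, PeakSet
from .sc_preprocess import CountMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "MultiomePair",
    "make_program_cohort",
    "make_multiome_pair",
    "make_fragments",
    "make_cohort_tables",
]

_N_MITO = 10  # leading genes named with the mitochondrial prefix


@dataclass
class SimulationConfig:
    n_samples: int = 3
    n_genes: int = 500
    n_cells_per_sample: int = 300
    n_shared_programs: int = 3
    n_private_programs_per_sample: int = 1
    program_gene_fraction: float = 0.05
    usage_concentration: float = 0.3   # Dirichlet alpha; 0 = one-hot usages
    library_size_mean: float = 2000.0
    noise_level: float = 0.1
    tf_coupling: float = 2.0
    n_peaks: int = 1000
    motif_density: float = 0.02
    n_motifs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_cells_per_sample",
                     "n_peaks", "n_motifs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_shared_programs < 0 or self.n_private_programs_per_sample < 0:
            raise ValueError("program counts must be >= 0")
        if self.n_shared_programs + self.n_private_programs_per_sample < 1:
            raise ValueError("each sample needs at least one program")
        for name in ("program_gene_fraction", "motif_density"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.noise_level < 0 or self.usage_concentration < 0 or self.tf_coupling < 0:
            raise ValueError("noise_level, usage_concentration and tf_coupling must be >= 0")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")


@dataclass
class GroundTruth:
    true_spectra: np.ndarray              # programs x genes (rows sum to 1)
    true_usage: np.ndarray                # cells x programs (rows sum to 1)
    barcodes: np.ndarray
    programs_by_sample: dict[str, list[int]]   # sample -> global program ids
    shared_program_ids: list[int]
    program_genes: list[list[str]] = field(default_factory=list)
    planted_tf: str | None = None
    planted_module_cells: np.ndarray | None = None


@dataclass
class MultiomePair:
    rna: CountMatrix
    fragments: FragmentSet
    peaks: PeakSet
    motifs: MotifAnnotationMatrix
    truth: GroundTruth
    gene_models: pd.DataFrame


def _gene_ids(n_genes: int, mito_prefix: str = "MT-") -> np.ndarray:
    n_mito = min(_N_MITO, max(1, n_genes // 20))
    ids = [f"{mito_prefix}{i:02d}" for i in range(n_mito)]
    ids += [f"GENE{i:05d}" for i in range(n_genes - n_mito)]
    return np.array(ids, dtype=object)


def _build_spectra(cfg: SimulationConfig, rng: np.random.Generator,
                   n_programs: int, gene_ids: np.ndarray) -> tuple[np.ndarray, list[list[str]]]:
    """Disjoint gene blocks per program with gamma-distributed weights."""
    n_mito = sum(str(g).startswith("MT-") for g in gene_ids)
    usable = np.arange(n_mito, cfg.n_genes)
    block = max(2, round(cfg.program_gene_fraction * cfg.n_genes))
    if n_programs * block > len(usable):
        raise ValueError("programs x block size exceeds the available genes; "
                         "lower program_gene_fraction or the program count")
    spectra = np.zeros((n_programs, cfg.n_genes))
    program_genes: list[list[str]] = []
    for p in range(n_programs):
        genes = usable[p * block:(p + 1) * block]
        spectra[p, genes] = rng.gamma(shape=2.0, scale=1.0, size=block) + 0.1
        spectra[p] /= spectra[p].sum()
        program_genes.append([str(gene_ids[g]) for g in genes])
    return spectra, program_genes


def _draw_usage(rng: np.random.Generator, n_cells: int, programs: list[int],
                n_programs_total: int, alpha: float) -> np.ndarray:
    usage = np.zeros((n_cells, n_programs_total))
    k = len(programs)
    if alpha == 0:
        choice = rng.integers(0, k, size=n_cells)
        usage[np.arange(n_cells), np.asarray(programs)[choice]] = 1.0
    else:
        usage[:, programs] = rng.dirichlet(np.full(k, alpha), size=n_cells)
    return usage


def _background(cfg: SimulationConfig, gene_ids: np.ndarray) -> np.ndarray:
    """Off-program Poisson background; mitochondrial genes get extra weight."""
    b = np.ones(cfg.n_genes)
    mito = np.array([str(g).startswith("MT-") for g in gene_ids])
    b[mito] = 5.0
    return b / b.sum()


def make_program_cohort(cfg: SimulationConfig,
                        require_recoverable: bool = False
                        ) -> tuple[list[CountMatrix], GroundTruth]:
    """Multi-sample count matrices mixing shared and private programs.

    The expected count of gene g in cell c is
    library_size * sum_p usage[c,p] * spectra[p,g] + noise, with Poisson
    observation noise; shared programs enter every sample's generative model,
    private programs exactly one.
    """
    if require_recoverable and cfg.n_shared_programs == 0:
        raise ValueError("recurrent-program recovery needs n_shared_programs >= 1")
    rng = np.random.default_rng(cfg.seed)
    gene_ids = _gene_ids(cfg.n_genes)
    n_total = cfg.n_shared_programs + cfg.n_samples * cfg.n_private_programs_per_sample
    spectra, program_genes = _build_spectra(cfg, rng, n_total, gene_ids)
    background = _background(cfg, gene_ids)
    shared_ids = list(range(cfg.n_shared_programs))
    matrices: list[CountMatrix] = []
    usages, barcodes_all = [], []
    programs_by_sample: dict[str, list[int]] = {}
    for s in range(cfg.n_samples):
        sample = f"S{s}"
        private = [cfg.n_shared_programs + s * cfg.n_private_programs_per_sample + j
                   for j in range(cfg.n_private_programs_per_sample)]
        programs = shared_ids + private
        programs_by_sample[sample] = programs
        usage = _draw_usage(rng, cfg.n_cells_per_sample, programs, n_total,
                            cfg.usage_concentration)
        lib = rng.lognormal(mean=np.log(cfg.library_size_mean) - 0.045, sigma=0.3,
                            size=cfg.n_cells_per_sample)
        lam = lib[:, None] * (usage @ spectra)          # cells x genes
        lam += cfg.noise_level * lib[:, None] * background[None, :]
        counts = rng.poisson(lam).T                      # genes x cells
        bcs = np.array([f"{sample}_CELL{i:04d}" for i in range(cfg.n_cells_per_sample)],
                       dtype=object)
        matrices.append(CountMatrix(sp.csr_matrix(counts), gene_ids, bcs,
                                    np.full(cfg.n_cells_per_sample, sample, dtype=object)))
        usages.append(usage)
        barcodes_all.append(bcs)
    truth = GroundTruth(
        true_spectra=spectra,
        true_usage=np.vstack(usages),
        barcodes=np.concatenate(barcodes_all),
        programs_by_sample=programs_by_sample,
        shared_program_ids=shared_ids,
        program_genes=program_genes,
    )
    return matrices, truth


def make_multiome_pair(cfg: SimulationConfig) -> MultiomePair:
    """Paired RNA and ATAC arms over the same cells with one planted TF.

    Each gene owns a promoter peak; the remaining peaks are intergenic. The
    planted TF's motif covers the promoter peaks of program-1's genes (plus
    random peaks at ``motif_density``), and the accessibility rate of every
    motif-carrying peak is multiplied by (1 + tf_coupling * program-1 usage),
    so both the motif deviations and the gene-activity module score of the
    program-1 gene set track the planted usage. Peak GC content is uniform on
    [0.3, 0.7].
    """
    if cfg.n_peaks < cfg.n_genes + 10:
        raise ValueError("need n_peaks >= n_genes + 10 (one promoter peak per "
                         "gene plus intergenic peaks)")
    rng = np.random.default_rng(cfg.seed)
    gene_ids = _gene_ids(cfg.n_genes)
    n_cells = cfg.n_cells_per_sample
    sample = "S0"
    n_programs = max(cfg.n_shared_programs, 2)
    spectra, program_genes = _build_spectra(cfg, rng, n_programs, gene_ids)
    usage = _draw_usage(rng, n_cells, list(range(n_programs)), n_programs,
                        cfg.usage_concentration)
    background = _background(cfg, gene_ids)
    lib = rng.lognormal(mean=np.log(cfg.library_size_mean) - 0.045, sigma=0.3, size=n_cells)
    lam = lib[:, None] * (usage @ spectra) + cfg.noise_level * lib[:, None] * background[None, :]
    counts = rng.poisson(lam).T
    barcodes = np.array([f"{sample}_CELL{i:04d}" for i in range(n_cells)], dtype=object)
    rna = CountMatrix(sp.csr_matrix(counts), gene_ids, barcodes,
                      np.full(n_cells, sample, dtype=object))

    # genome layout: one chromosome, genes every 5 kb with a 500 bp promoter
    # peak centered on the TSS, intergenic peaks downstream every 2 kb
    gene_spacing, peak_width = 5000, 500
    tss = 10_000 + np.arange(cfg.n_genes) * gene_spacing
    gene_end = tss + 2000
    gene_models = pd.DataFrame({"gene": gene_ids, "chrom": "chr1",
                                "strand": "+", "tss": tss, "end": gene_end})
    promoter_start = tss - peak_width // 2
    n_intergenic = cfg.n_peaks - cfg.n_genes
    inter_start = gene_end[-1] + 10_000 + np.arange(n_intergenic) * 2000
    starts = np.concatenate([promoter_start, inter_start])
    ends = starts + peak_width
    genome = {"chr1": int(ends[-1] + 10_000)}
    peaks = PeakSet(chrom=np.full(cfg.n_peaks, "chr1", dtype=object),
                    start=starts, end=ends,
                    gc_content=rng.uniform(0.3, 0.7, size=cfg.n_peaks))

    # motif annotations: random at motif_density; with a nonzero coupling the
    # planted motif (first id) additionally covers the promoter peaks of
    # program 1's genes — the planted TF's regulon. At tf_coupling == 0 there
    # is no TF-program link and the "planted" motif is exchangeable with any
    # other motif.
    membership = rng.random((cfg.n_peaks, cfg.n_motifs)) < cfg.motif_density
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    program1_peaks = np.array([gene_index[g] for g in program_genes[0]])
    if cfg.tf_coupling > 0:
        membership[program1_peaks, 0] = True
    motif_ids = np.array([f"M{i:03d}" for i in range(cfg.n_motifs)], dtype=object)
    motifs = MotifAnnotationMatrix(sp.csr_matrix(membership), motif_ids)

    # fragment counts: per-cell depth split across peaks by relative rates;
    # planted-motif peaks boosted by (1 + tf_coupling * program-1 usage)
    base = rng.gamma(shape=2.0, scale=1.0, size=cfg.n_peaks) + 0.2
    boosted = np.asarray(membership[:, 0]).ravel()
    u1 = usage[:, 0]
    rates = np.tile(base, (n_cells, 1))
    rates[:, boosted] *= (1.0 + cfg.tf_coupling * u1)[:, None]
    rates /= rates.sum(axis=1, keepdims=True)
    depth = rng.lognormal(mean=np.log(3000.0) - 0.02, sigma=0.2, size=n_cells)
    nfrag = rng.poisson(depth[:, None] * rates / 2.0)   # each fragment = 2 insertions
    cell_idx, peak_idx = np.nonzero(nfrag)
    reps = nfrag[cell_idx, peak_idx]
    cell_idx = np.repeat(cell_idx, reps)
    peak_idx = np.repeat(peak_idx, reps)
    frag_len = rng.integers(80, 201, size=len(peak_idx))
    offset = rng.integers(0, peak_width - 200, size=len(peak_idx))
    frag_start = starts[peak_idx] + offset
    fragments = FragmentSet(
        chrom=np.full(len(peak_idx), "chr1", dtype=object),
        start=frag_start,
        end=frag_start + frag_len,
        barcode=barcodes[cell_idx],
        count=np.ones(len(peak_idx), dtype=np.int64),
        genome=genome,
    )
    q3 = np.quantile(u1, 0.75)
    truth = GroundTruth(
        true_spectra=spectra,
        true_usage=usage,
        barcodes=barcodes,
        programs_by_sample={sample: list(range(n_programs))},
        shared_program_ids=list(range(n_programs)),
        program_genes=program_genes,
        planted_tf=str(motif_ids[0]),
        planted_module_cells=barcodes[u1 >= q3],
    )
    return MultiomePair(rna=rna, fragments=fragments, peaks=peaks,
                        motifs=motifs, truth=truth, gene_models=gene_models)


def make_fragments(n_cells: int, frags_per_cell: float, tss_fraction: float,
                   tss_positions: np.ndarray, seed: int = 0,
                   window: int = 2000) -> FragmentSet:
    """Fragments with a controlled fraction of TSS-proximal starts.

    A fraction ``tss_fraction`` of fragments start within +/-50 bp of a
    (uniformly chosen) TSS; the remainder start uniformly within
    +/-``window`` bp of a TSS, so tss_fraction=0 gives flat insertion density
    and a TSS enrichment near 1.
    """
    if not (0 <= tss_fraction <= 1):
        raise ValueError("tss_fraction must lie in [0, 1]")
    tss_positions = np.sort(np.asarray(tss_positions, dtype=np.int64))
    if len(tss_positions) == 0:
        raise ValueError("need at least one TSS")
    rng = np.random.default_rng(seed)
    nfrag = rng.poisson(frags_per_cell, size=n_cells)
    total = int(nfrag.sum())
    barcode = np.repeat(np.array([f"BC{i:05d}" for i in range(n_cells)], dtype=object), nfrag)
    site = tss_positions[rng.integers(0, len(tss_positions), size=total)]
    at_tss = rng.random(total) < tss_fraction
    length = rng.integers(80, 201, size=total)
    # background starts span [-window-length, +window] so that both fragment
    # ends have flat density across the whole +/-window region
    lo = -window - length + 1
    span = 2 * window + length
    bg_offs = lo + (rng.random(total) * span).astype(np.int64)
    offs = np.where(at_tss, rng.integers(-50, 51, size=total), bg_offs)
    start = np.maximum(site + offs, 0)
    genome = {"chr1": int(tss_positions[-1] + window + 1000)}
    return FragmentSet(chrom=np.full(total, "chr1", dtype=object),
                       start=start, end=start + length, barcode=barcode,
                       count=np.ones(total, dtype=np.int64), genome=genome)


def make_cohort_tables() -> tuple[np.ndarray, dict[str, list[float]]]:
    """The printed cohort inputs: the 2x2 engraftment-metastasis table
    (rows = metastasis-derived / primary-derived organoids, columns =
    metastasis yes/no) and the per-group passage intervals in days."""
    table = np.array([[4, 2], [2, 11]], dtype=np.int64)
    passage_intervals = {
        "primary": [7, 7, 7, 14, 6, 7, 9, 9, 14, 9, 7, 16],
        "metastasis": [10, 7, 12, 12, 10, 10, 12],
    }
    return table, passage_intervals
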