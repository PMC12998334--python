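"""Convenience workflows chaining the module-level operations.

These are thin orchestration helpers used by the example scripts and the
reproduction script; every step is an ordinary public function from the
stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import atac_scores as atac
from . import gep_programs as gep
from . import regulator_integration as reg
from . import sc_preprocess as pp
from .sc_preprocess import CountMatrix
from .synthetic_data import MultiomePair

__all__ = ["RPResult", "discover_recurrent_programs", "RegulatorResult",
           "infer_regulators"]


@dataclass
class RPResult:
    signatures: list = field(repr=False)
    jaccard: pd.DataFrame = field(repr=False)
    recurrent_programs: list = field(repr=False)
    chosen_ranks: dict[str, int] = field(default_factory=dict)
    rank_selections: dict = field(default_factory=dict, repr=False)

    @property
    def multi_sample(self) -> list:
        return [rp for rp in self.recurrent_programs
                if len({s for s, _ in rp.members}) > 1]


def _nmf_matrix(m: CountMatrix, n_hvg: int):
    nm = pp.normalize_log(m)
    hvg = pp.select_hvg(nm, pp.HVGParams(n_hvg=min(n_hvg, m.n_genes)))
    idx = {g: i for i, g in enumerate(nm.gene_ids)}
    rows = [idx[g] for g in hvg]
    return gep.nmf_input(nm.dense()[rows]), nm.gene_ids[rows]


def discover_recurrent_programs(matrices: list[CountMatrix], n_rp: int,
                                k_range=range(4, 10), n_restarts: int = 8,
                                n_hvg: int = 200, n_top: int = 30,
                                min_frac: float = 1 / 3,
                                seed: int = 0) -> RPResult:
    """Per-sample rank selection + consensus NMF, then cross-sample
    consolidation of top-gene signatures into recurrent programs."""
    signatures, ranks, selections = [], {}, {}
    for m in matrices:
        sample = str(m.sample_labels[0])
        X, gids = _nmf_matrix(m, n_hvg)
        sel = gep.select_rank(X, k_range, n_restarts=n_restarts, seed=seed,
                              gene_ids=gids, sample_id=sample)
        ranks[sample] = sel.chosen_k
        selections[sample] = sel
        spectra, _ = gep.consensus_nmf(X, sel.chosen_k, n_restarts=n_restarts,
                                       seed=seed, gene_ids=gids, sample_id=sample)
        signatures += gep.top_genes(spectra, n_top=n_top)
    jac = gep.jaccard_matrix(signatures)
    rps = gep.consolidate_programs(signatures, n_rp=n_rp, min_frac=min_frac)
    return RPResult(signatures, jac, rps, ranks, selections)


@dataclass
class RegulatorResult:
    deviations: object = field(repr=False)
    module_score_matrix: object = field(repr=False)
    correlations: pd.DataFrame = field(repr=False)
    ranking: dict[str, pd.Series] = field(default_factory=dict, repr=False)

    def top_motif(self, module: str) -> str:
        return str(self.ranking[module].index[0])


def infer_regulators(mp: MultiomePair, modules: dict[str, list[str]],
                     n_bg: int = 50, seed: int = 0) -> RegulatorResult:
    """ATAC peak counting, chromVAR deviations, gene-activity module scores
    and module x motif correlation ranking for a paired multiome."""
    pm = atac.peak_cell_matrix(mp.fragments, mp.peaks, mp.rna.barcodes)
    bg = atac.background_peaks(pm, mp.peaks, n_bg=n_bg, seed=seed)
    dz = atac.motif_deviations(pm, mp.motifs, bg)
    ga = atac.gene_activity(mp.fragments, mp.gene_models, mp.rna.barcodes)
    ms = reg.module_scores(ga.scores, ga.gene_ids, ga.barcodes, modules, seed=seed)
    mmc = reg.module_motif_correlation(ms, dz)
    ranking = {str(mod): reg.rank_regulators(mmc.loc[mod]) for mod in mmc.index}
    return RegulatorResult(dz, ms, mmc, ranking)
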