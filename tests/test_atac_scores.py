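"""ATAC scoring: QC boundary semantics, insertion-counting conventions, LSI
separation, gene-activity weights, matched background draws and the chromVAR
deviation identities."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats
from sklearn.metrics import silhouette_score

from periprog import atac_scores as atac
from periprog.atac_scores import (AtacQCParams, BackgroundPeaks, FragmentSet,
                                  MotifAnnotationMatrix, PeakMatrix, PeakSet)
from periprog.synthetic_data import SimulationConfig, make_fragments, make_multiome_pair

TSS = (np.arange(1, 21) * 10_000).astype(int)


def _frags(rows, genome=None):
    chrom, start, end, bc, count = zip(*rows)
    return FragmentSet(np.array(chrom, dtype=object), np.array(start),
                       np.array(end), np.array(bc, dtype=object),
                       np.array(count), genome=genome or {})


class TestTSSEnrichment:
    def test_all_tss_insertions_capped(self):
        rows = [("chr1", int(t) - 10, int(t) + 90, "BC0", 1) for t in TSS]
        scores = atac.tss_enrichment(_frags(rows), {"chr1": TSS})
        assert scores["BC0"] == AtacQCParams().max_score

    def test_distal_only_barcode_scores_zero(self):
        rows = [("chr1", 5000, 5100, "BC0", 1)]  # >2 kb from every TSS
        scores = atac.tss_enrichment(_frags(rows), {"chr1": TSS})
        assert scores["BC0"] == 0.0

    def test_uniform_density_scores_near_one(self):
        frags = make_fragments(30, 5000, 0.0, TSS, seed=4)
        scores = atac.tss_enrichment(frags, {"chr1": TSS})
        assert np.all(np.abs(scores.to_numpy() - 1.0) < 0.3)


class TestFragmentQC:
    def _bulk_frags(self, barcode, n_unique):
        return [("chr1", 1000 + 10 * i, 1100 + 10 * i, barcode, 1)
                for i in range(n_unique)]

    def test_boundary_semantics(self):
        frags = _frags(self._bulk_frags("LOW", 1499) + self._bulk_frags("OK", 1500))
        scores = pd.Series({"LOW": 10.0, "OK": 4.0})
        kept = atac.fragment_qc(frags, scores)
        assert list(kept) == ["OK"]  # 1499 unique removed; exactly 1500 & score 4 kept

    def test_duplicates_do_not_count_as_unique(self):
        rows = self._bulk_frags("DUP", 800) * 2
        kept = atac.fragment_qc(_frags(rows), pd.Series({"DUP": 10.0}))
        assert len(kept) == 0


class TestPeakCellMatrix:
    PEAKS = PeakSet(np.array(["chr1"], dtype=object), np.array([1000]),
                    np.array([1500]), np.array([0.5]))

    @pytest.mark.parametrize("start,end,expected", [
        (1100, 1300, 2),   # fully inside: both insertions counted
        (900, 1600, 0),    # spans the peak, both ends outside
        (1400, 1600, 1),   # start inside, end outside
        (900, 1200, 1),    # end-1 inside, start outside
    ])
    def test_insertion_conventions(self, start, end, expected):
        pm = atac.peak_cell_matrix(_frags([("chr1", start, end, "B", 1)]),
                                   self.PEAKS, np.array(["B"], dtype=object))
        assert pm.counts[0, 0] == expected

    def test_duplicate_count_weighting(self):
        pm = atac.peak_cell_matrix(_frags([("chr1", 1100, 1300, "B", 3)]),
                                   self.PEAKS, np.array(["B"], dtype=object))
        assert pm.counts[0, 0] == 6

    def test_overlapping_peaks_rejected(self):
        with pytest.raises(ValueError, match="merge"):
            PeakSet(np.array(["chr1", "chr1"], dtype=object), np.array([100, 400]),
                    np.array([500, 900]), np.array([0.5, 0.5]))

    def test_total_equals_contained_insertions(self, multiome):
        pm = atac.peak_cell_matrix(multiome.fragments, multiome.peaks,
                                   multiome.rna.barcodes)
        # generator places every fragment fully inside one peak
        assert pm.counts.sum() == 2 * multiome.fragments.count.sum()


class TestEmbedLSI:
    def _pm(self, C):
        return PeakMatrix(sp.csr_matrix(C),
                          np.array([f"B{i}" for i in range(C.shape[1])], dtype=object))

    def test_disjoint_blocks_separate(self):
        rng = np.random.default_rng(0)
        C = np.zeros((200, 100))
        C[:100, :50] = rng.poisson(3, (100, 50))
        C[100:, 50:] = rng.poisson(3, (100, 50))
        emb = atac.embed_lsi(self._pm(C), n_dims=5, seed=0)
        assert silhouette_score(emb.coordinates, [0] * 50 + [1] * 50) > 0.9

    def test_duplicated_input_identical(self):
        C = np.random.default_rng(1).poisson(2, (80, 40))
        a = atac.embed_lsi(self._pm(C), n_dims=6, seed=0)
        b = atac.embed_lsi(self._pm(C), n_dims=6, seed=0)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_constant_matrix_flagged(self):
        C = np.zeros((50, 10))
        with pytest.warns(UserWarning, match="degenerate"):
            emb = atac.embed_lsi(self._pm(C), n_dims=4, seed=0)
        assert np.allclose(emb.coordinates, 0.0)


class TestGeneActivity:
    # two genes far apart; gene B acts as the reference for weight ratios
    # (per-cell depth normalization preserves between-gene ratios)
    MODELS = pd.DataFrame({"gene": ["GA", "GB"], "chrom": ["chr1", "chr1"],
                           "strand": ["+", "+"], "tss": [50_000, 500_000],
                           "end": [52_000, 502_000]})
    REF = ("chr1", 500_500, 500_700, "B", 1)  # fully inside GB's body: weight 2

    def _ratio(self, row):
        ga = atac.gene_activity(_frags([row, self.REF]), self.MODELS,
                                np.array(["B"], dtype=object))
        return np.expm1(ga.scores[0, 0]) / np.expm1(ga.scores[1, 0])

    def test_insertion_at_tss_weighs_one(self):
        # both insertions of a fragment at GA's TSS: same weight as the reference
        assert self._ratio(("chr1", 50_000, 50_200, "B", 1)) == pytest.approx(1.0)

    def test_upstream_decay_weight(self):
        # both insertions exactly 5 kb upstream of the 48 kb promoter edge
        assert self._ratio(("chr1", 43_000, 43_001, "B", 1)) == pytest.approx(np.exp(-1))

    def test_bad_gene_model_named(self):
        bad = pd.DataFrame({"gene": ["BAD"], "chrom": ["chr1"], "strand": ["?"],
                            "tss": [100], "end": [200]})
        with pytest.raises(ValueError, match="BAD"):
            atac.gene_activity(_frags([("chr1", 10, 50, "B", 1)]), bad,
                               np.array(["B"], dtype=object))

    def test_module_activity_tracks_planted_usage(self, multiome):
        from periprog.regulator_integration import module_score

        ga = atac.gene_activity(multiome.fragments, multiome.gene_models,
                                multiome.rna.barcodes)
        score = module_score(ga.scores, ga.gene_ids,
                             multiome.truth.program_genes[0], seed=3)
        r = np.corrcoef(score, multiome.truth.true_usage[:, 0])[0, 1]
        assert r > 0.4


class TestBackgroundPeaks:
    def test_uniform_over_identical_peaks(self):
        n = 100
        pm = PeakMatrix(sp.csr_matrix(np.ones((n, 5))),
                        np.array([f"B{i}" for i in range(5)], dtype=object))
        pk = PeakSet(np.full(n, "chr1", dtype=object), np.arange(n) * 1000,
                     np.arange(n) * 1000 + 500, np.full(n, 0.5))
        bg = atac.background_peaks(pm, pk, n_bg=100, seed=1)
        counts = np.bincount(bg.indices.ravel(), minlength=n)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_single_peak_background_is_self(self):
        pm = PeakMatrix(sp.csr_matrix(np.ones((1, 3))),
                        np.array(["B0", "B1", "B2"], dtype=object))
        pk = PeakSet(np.array(["chr1"], dtype=object), np.array([0]),
                     np.array([500]), np.array([0.5]))
        bg = atac.background_peaks(pm, pk, n_bg=5, seed=0)
        assert np.all(bg.indices == 0)

    def test_seeded_draws_deterministic(self, multiome):
        pm = atac.peak_cell_matrix(multiome.fragments, multiome.peaks,
                                   multiome.rna.barcodes)
        a = atac.background_peaks(pm, multiome.peaks, n_bg=10, seed=9)
        b = atac.background_peaks(pm, multiome.peaks, n_bg=10, seed=9)
        assert np.array_equal(a.indices, b.indices)

    def test_preserves_gc_distribution(self):
        rng = np.random.default_rng(0)
        n = 300
        gc = rng.uniform(0.3, 0.7, n)
        C = rng.poisson(rng.gamma(2, 1, n)[:, None] * np.ones((1, 20)))
        pm = PeakMatrix(sp.csr_matrix(C),
                        np.array([f"B{i}" for i in range(20)], dtype=object))
        pk = PeakSet(np.full(n, "chr1", dtype=object), np.arange(n) * 1000,
                     np.arange(n) * 1000 + 500, gc)
        bg = atac.background_peaks(pm, pk, n_bg=50, seed=2, n_neighbors=25)
        matched = np.abs(gc[bg.indices] - gc[:, None]).mean()
        random = np.abs(gc[rng.integers(0, n, size=bg.indices.shape)] - gc[:, None]).mean()
        assert matched < random


class TestMotifDeviations:
    def _toy(self):
        counts = np.array([[4, 0], [1, 1], [1, 3]])
        pm = PeakMatrix(sp.csr_matrix(counts), np.array(["c1", "c2"], dtype=object))
        ma = MotifAnnotationMatrix(sp.csr_matrix(np.array([[1], [0], [0]], dtype=bool)),
                                   np.array(["m"], dtype=object))
        bg = BackgroundPeaks(np.array([[1, 2], [0, 2], [0, 1]]))
        return pm, ma, bg

    def test_hand_computed_raw_deviations(self):
        dz = atac.motif_deviations(*self._toy())
        assert dz.raw[0] == pytest.approx([(4 - 2.4) / 2.4, (0 - 1.6) / 1.6])

    def test_motif_covering_all_peaks_is_exactly_zero(self):
        pm, _, bg = self._toy()
        ma = MotifAnnotationMatrix(sp.csr_matrix(np.ones((3, 1), dtype=bool)),
                                   np.array(["all"], dtype=object))
        dz = atac.motif_deviations(pm, ma, bg)
        assert np.allclose(dz.raw, 0.0)

    def test_single_cell_raw_zero(self):
        counts = np.array([[4], [1], [2]])
        pm = PeakMatrix(sp.csr_matrix(counts), np.array(["c1"], dtype=object))
        ma = MotifAnnotationMatrix(sp.csr_matrix(np.array([[1], [0], [1]], dtype=bool)),
                                   np.array(["m"], dtype=object))
        bg = BackgroundPeaks(np.zeros((3, 2), dtype=int))
        dz = atac.motif_deviations(pm, ma, bg)
        assert np.allclose(dz.raw, 0.0)

    def test_expectation_conservation(self, multiome, regulator_result):
        pm = atac.peak_cell_matrix(multiome.fragments, multiome.peaks,
                                   multiome.rna.barcodes)
        C = np.asarray(pm.counts.todense(), dtype=float)
        M = np.asarray(multiome.motifs.membership.todense(), dtype=float)
        X = M.T @ C
        totals = C.sum(axis=0)
        frac = (M.T @ C.sum(axis=1)) / C.sum()
        E = np.outer(frac, totals)
        imbalance = np.abs(X.sum(axis=1) - E.sum(axis=1))
        assert imbalance.max() < 1e-9 * max(1.0, C.sum())

    def test_planted_deviation_tracks_usage(self, multiome, regulator_result):
        z = regulator_result.deviations.z[0]  # planted motif is the first id
        r = np.corrcoef(z, multiome.truth.true_usage[:, 0])[0, 1]
        assert r > 0.3

    def test_null_coupling_deviation_uncorrelated(self):
        from periprog.workflows import infer_regulators

        cfg = SimulationConfig(seed=21, n_cells_per_sample=300, tf_coupling=0.0)
        mp = make_multiome_pair(cfg)
        pm = atac.peak_cell_matrix(mp.fragments, mp.peaks, mp.rna.barcodes)
        bg = atac.background_peaks(pm, mp.peaks, n_bg=25, seed=21)
        dz = atac.motif_deviations(pm, mp.motifs, bg)
        planted = list(dz.motif_ids).index(mp.truth.planted_tf)
        r = np.corrcoef(dz.z[planted], mp.truth.true_usage[:, 0])[0, 1]
        assert abs(r) < 0.1
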