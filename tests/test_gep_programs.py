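"""Consensus NMF and recurrent-program consolidation: exact small cases,
monotonicity, restart robustness, rank selection, the one-third rule, and
hypergeometric overlap oracles."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from periprog import gep_programs as gep
from periprog.gep_programs import (GeneSignature, cluster_programs,
                                   consensus_from_pool, consensus_nmf,
                                   define_rp_genes, jaccard_matrix,
                                   nmf_factorize, overlap_test, overlap_tests,
                                   select_rank, top_genes)
from periprog.workflows import _nmf_matrix
from periprog.synthetic_data import SimulationConfig, make_program_cohort


def hypergeom_tail_enum(i, N, a, b):
    """Upper-tail P(X >= i) by direct term enumeration."""
    return sum(math.comb(a, j) * math.comb(N - a, b - j) for j in range(i, min(a, b) + 1)) / math.comb(N, b)


class TestNMF:
    def test_exact_rank_one(self):
        rng = np.random.default_rng(0)
        w, h = rng.uniform(0.5, 2, 12), rng.uniform(0.5, 2, 9)
        X = np.outer(w, h)
        spectra, usage = nmf_factorize(X, k=1, seed=0, max_iter=2000, tol=1e-12)
        assert spectra.error_history[-1] < 1e-4
        cos = (spectra.weights[0] @ w) / (np.linalg.norm(spectra.weights[0]) * np.linalg.norm(w))
        assert cos > 0.999

    def test_error_sequence_monotone(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            X = rng.gamma(1.0, 1.0, size=(15, 20))
            spectra, _ = nmf_factorize(X, k=3, seed=int(rng.integers(1e6)), max_iter=80)
            errs = np.array(spectra.error_history)
            assert np.all(np.diff(errs) <= 1e-10)

    def test_disjoint_block_programs(self):
        # 6 genes x 8 cells, two disjoint 3-gene programs
        X = np.zeros((6, 8))
        X[:3, :4] = [[4, 5, 3, 4], [2, 3, 2, 2], [6, 5, 7, 6]]
        X[3:, 4:] = [[3, 4, 3, 3], [5, 5, 6, 4], [1, 2, 1, 1]]
        spectra, _ = nmf_factorize(X, k=2, seed=0, max_iter=2000)
        tops = {frozenset(s.genes) for s in top_genes(spectra, n_top=3)}
        assert tops == {frozenset({"g0", "g1", "g2"}), frozenset({"g3", "g4", "g5"})}

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            nmf_factorize(np.array([[1.0, -1.0], [0.0, 2.0], [1.0, 1.0]]), k=1)


class TestConsensus:
    def test_identical_seeds_equal_single_run(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.normal(2, 1, size=(30, 40)))
        single, _ = nmf_factorize(X, 3, seed=5)
        cons, _ = consensus_nmf(X, 3, seeds=[5, 5], seed=0)
        w = single.weights / np.linalg.norm(single.weights, axis=1, keepdims=True)
        sims = cons.weights @ w.T
        from scipy.optimize import linear_sum_assignment
        r, c = linear_sum_assignment(-sims)
        assert sims[r, c].min() > 0.9999

    def test_corrupted_restart_filtered_out(self):
        rng = np.random.default_rng(0)
        clean = rng.gamma(2, 1, size=(3, 50))
        clean[:, 40:] = 0.0
        clean /= np.linalg.norm(clean, axis=1, keepdims=True)
        pool_clean = np.abs(np.vstack([clean + rng.normal(0, 0.002, clean.shape)
                                       for _ in range(7)]))
        corrupt = np.zeros((3, 50))  # far-off local optimum: lone single-gene spikes
        corrupt[0, 40] = corrupt[1, 43] = corrupt[2, 47] = 1.0
        with_corrupt = consensus_from_pool(np.vstack([pool_clean, corrupt]), 3,
                                           n_restarts=8, density_threshold=0.5, seed=0)
        clean_only = consensus_from_pool(pool_clean, 3, n_restarts=7,
                                         density_threshold=0.5, seed=0)
        assert np.allclose(with_corrupt, clean_only, atol=1e-9)

    def test_overstrict_threshold_raises(self):
        rng = np.random.default_rng(3)
        X = np.abs(rng.normal(2, 1, size=(20, 30)))
        with pytest.raises(ValueError, match="density_threshold"):
            consensus_nmf(X, 3, n_restarts=4, density_threshold=-1.0, seed=0)


class TestSelectRank:
    def test_singleton_range(self):
        X = np.abs(np.random.default_rng(4).normal(2, 1, size=(30, 40)))
        assert select_rank(X, k_range=[4], n_restarts=4, seed=0).chosen_k == 4

    def test_recovers_planted_rank(self):
        cfg = SimulationConfig(n_samples=1, n_shared_programs=5,
                               n_private_programs_per_sample=0,
                               noise_level=0.05, seed=7)
        mats, _ = make_program_cohort(cfg)
        X, _ = _nmf_matrix(mats[0], n_hvg=200)
        assert select_rank(X, range(4, 10), n_restarts=8, seed=0).chosen_k == 5

    def test_pure_noise_falls_to_smallest_k(self):
        rng = np.random.default_rng(11)
        X = gep.nmf_input(rng.poisson(1.0, size=(150, 200)).astype(float))
        assert select_rank(X, range(4, 10), n_restarts=8, seed=11).chosen_k == 4


class TestSignatures:
    def _spectra(self, weights, gene_ids):
        return gep.ProgramSpectra(np.asarray(weights, dtype=float),
                                  np.array(gene_ids, dtype=object), sample_id="s")

    def test_top_genes_ordering_and_tie_rule(self):
        s = self._spectra([[3, 2, 2, 1]], ["g1", "g3", "g2", "g4"])
        assert top_genes(s, n_top=2)[0].genes == ["g1", "g2"]  # tie broken by id

    def test_top_genes_truncation(self):
        s = self._spectra([[3, 2, 1]], ["a", "b", "c"])
        assert top_genes(s, n_top=10)[0].genes == ["a", "b", "c"]

    def test_jaccard_analytic_values(self):
        sigs = [GeneSignature("p0", "s", [f"g{i}" for i in range(200)]),
                GeneSignature("p1", "s", [f"g{i}" for i in range(200)]),
                GeneSignature("p2", "s", [f"g{i}" for i in range(100, 300)]),
                GeneSignature("p3", "s", [f"h{i}" for i in range(200)])]
        J = jaccard_matrix(sigs)
        assert J.loc["p0", "p1"] == 1.0
        assert J.loc["p0", "p3"] == 0.0
        assert J.loc["p0", "p2"] == pytest.approx(100 / 300)
        assert np.allclose(J, J.T) and np.allclose(np.diag(J), 1.0)
        assert (J.to_numpy() >= 0).all() and (J.to_numpy() <= 1).all()

    def test_cluster_programs_recovers_blocks(self):
        sigs = ([GeneSignature(f"a{i}", "s", [f"g{j}" for j in range(50)]) for i in range(3)]
                + [GeneSignature(f"b{i}", "s", [f"h{j}" for j in range(50)]) for i in range(3)])
        labels = cluster_programs(jaccard_matrix(sigs), n_rp=2)
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], labels) == 1.0

    def test_cluster_programs_singletons(self):
        sigs = [GeneSignature(f"p{i}", "s", [f"g{i}_{j}" for j in range(5)]) for i in range(4)]
        labels = cluster_programs(jaccard_matrix(sigs), n_rp=4)
        assert sorted(labels) == [0, 1, 2, 3]


class TestRPGenes:
    def _sigs(self, gene_lists):
        return [GeneSignature(f"p{i}", f"s{i}", genes)
                for i, genes in enumerate(gene_lists)]

    def test_one_third_boundary_inclusive(self):
        sigs = self._sigs([["a", "b"], ["b", "c"], ["b", "d"]])
        genes = define_rp_genes(sigs, min_frac=1 / 3)
        assert genes == {"a", "b", "c", "d"}  # 1/3 >= 1/3: included

    def test_below_one_third_excluded(self):
        sigs = self._sigs([["a", "b"], ["b"], ["b"], ["b"]])
        assert define_rp_genes(sigs, min_frac=1 / 3) == {"b"}  # "a" at 1/4 < 1/3

    def test_single_member_is_identity(self):
        sigs = self._sigs([["x", "y"]])
        assert define_rp_genes(sigs) == {"x", "y"}

    def test_min_frac_extremes_are_intersection_and_union(self):
        sigs = self._sigs([["a", "b", "c"], ["b", "c", "d"], ["c", "d", "e"]])
        assert define_rp_genes(sigs, min_frac=1.0) == {"c"}
        assert define_rp_genes(sigs, min_frac=1e-9) == {"a", "b", "c", "d", "e"}


class TestOverlap:
    def test_perfect_overlap_closed_form(self):
        a = {f"g{i}" for i in range(10)}
        res = overlap_test(a, a, universe=100)
        assert res.p == pytest.approx(1 / math.comb(100, 10), rel=1e-9)

    def test_empty_intersection_p_is_one(self):
        res = overlap_test({"a"}, {"b"}, universe=10)
        assert res.p == pytest.approx(1.0)

    def test_hand_enumerated_tail(self):
        a = {f"g{i}" for i in range(5)}
        b = {f"g{i}" for i in range(3)} | {"h1", "h2"}
        res = overlap_test(a, b, universe=20)
        assert res.p == pytest.approx(1126 / 15504, rel=1e-9)

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError):
            overlap_test({"a", "b"}, {"c"}, universe=2)

    def test_matches_enumeration_small_universes(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            N = int(rng.integers(5, 31))
            universe = [f"g{i}" for i in range(N)]
            a = set(rng.choice(universe, size=rng.integers(1, N // 2 + 1), replace=False))
            b = set(rng.choice(universe, size=rng.integers(1, N // 2 + 1), replace=False))
            res = overlap_test(a, b, N)
            expect = hypergeom_tail_enum(len(a & b), N, len(a), len(b))
            assert res.p == pytest.approx(expect, rel=1e-9)

    def test_batch_adjustment(self):
        rps = {"rp1": {"a", "b"}, "rp2": {"c"}}
        refs = {"r1": {"a"}, "r2": {"z"}}
        df = overlap_tests(rps, refs, universe=30)
        assert len(df) == 4
        assert (df.p_adj >= df.p - 1e-12).all()


class TestEndToEnd:
    def test_cohort_consolidation_recovers_shared_programs(self, default_cohort, rp_result):
        from tests.conftest import signature_truth_labels

        _, truth = default_cohort
        lab_truth = signature_truth_labels(rp_result.signatures, truth)
        lab_rp = cluster_programs(rp_result.jaccard, 6)
        assert adjusted_rand_score(lab_truth, lab_rp) == 1.0
        multi = rp_result.multi_sample
        assert len(multi) == len(truth.shared_program_ids)
        for rp in multi:
            samples = [s for s, _ in rp.members]
            assert sorted(samples) == ["S0", "S1", "S2"]


class TestRPActivity:
    def test_flat_matrix_scores_zero(self):
        import scipy.sparse as sp
        from periprog.sc_preprocess import NormalizedMatrix

        V = np.ones((40, 20))
        nm = NormalizedMatrix(sp.csr_matrix(V), np.array([f"G{i}" for i in range(40)], dtype=object),
                              np.array([f"C{i}" for i in range(20)], dtype=object))
        scores = gep.score_rp_activity(nm, {"rp0": {f"G{i}" for i in range(5)}}, seed=0)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_doubled_usage_detected_at_five_vs_five(self):
        from periprog import sc_preprocess as pp
        from periprog.cohort_stats import mann_whitney
        from periprog.regulator_integration import module_score

        cfg = SimulationConfig(n_samples=10, n_cells_per_sample=150, seed=13)
        mats, truth = make_program_cohort(cfg)
        met = set(range(5, 10))
        per_sample = []
        for s, m in enumerate(mats):
            X = np.asarray(m.X.todense())
            if s in met:  # metastasis-like: doubled program-1 expression
                idx = [list(m.gene_ids).index(g) for g in truth.program_genes[0]]
                X[idx] *= 2
            import scipy.sparse as sp
            nm = pp.normalize_log(pp.CountMatrix(sp.csr_matrix(X), m.gene_ids,
                                                 m.barcodes, m.sample_labels))
            sc = module_score(nm.dense(), nm.gene_ids, truth.program_genes[0], seed=13)
            per_sample.append(sc.mean())
        primary = [per_sample[i] for i in range(5)]
        metastasis = [per_sample[i] for i in met]
        assert np.mean(metastasis) > np.mean(primary)
        assert mann_whitney(primary, metastasis).p <= 0.05

        # permuted group labels: p behaves like a null
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(50):
            perm = rng.permutation(per_sample)
            if mann_whitney(perm[:5], perm[5:]).p < 0.05:
                hits += 1
        assert hits <= 5  # <= 10% of 50 permutations
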