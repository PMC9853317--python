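"""Gene activity, CCA co-embedding and minimum-cost cell pairing."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from scegrn.integration import (
    Embedding,
    evaluate_pairing,
    gene_activity_scores,
    joint_embedding,
    pair_cells,
)
from scegrn.io import CountMatrix, GeneAnnotation, Peak


def _counts(rng, n_feat, n_cells, prefix="f"):
    vals = rng.poisson(2.0, size=(n_feat, n_cells))
    return CountMatrix(
        sp.csr_matrix(vals),
        [f"{prefix}{i}" for i in range(n_feat)],
        [f"c{i}" for i in range(n_cells)],
    )


class TestGeneActivity:
    def _setup(self):
        peaks = [
            Peak("chr1", 1000, 1500),  # inside gene body
            Peak("chr1", 100, 300),  # upstream of TSS
            Peak("chr1", 9000, 9500),  # far downstream
        ]
        counts = np.array([[7, 1], [2, 0], [5, 5]])
        atac = CountMatrix(sp.csr_matrix(counts), ["p0", "p1", "p2"], ["a", "b"])
        gene = GeneAnnotation("G1", "chr1", "+", 900, 900, 3000)
        return atac, peaks, gene

    def test_peak_inside_window_counted(self):
        atac, peaks, gene = self._setup()
        act = gene_activity_scores(atac, peaks, [gene], upstream_bp=0)
        assert act.values[0, 0] == 7

    def test_upstream_zero_excludes_upstream_peak(self):
        atac, peaks, gene = self._setup()
        act = gene_activity_scores(atac, peaks, [gene], upstream_bp=0)
        assert act.values.toarray()[0].tolist() == [7, 1]  # p1, p2 excluded

    def test_upstream_window_includes_upstream_peak(self):
        atac, peaks, gene = self._setup()
        act = gene_activity_scores(atac, peaks, [gene], upstream_bp=800)
        assert act.values.toarray()[0].tolist() == [9, 1]

    def test_overlapping_genes_both_counted_brute_force(self):
        rng = np.random.default_rng(0)
        n_peaks, n_cells, n_genes = 40, 5, 8
        starts = rng.integers(0, 50_000, n_peaks)
        peaks = [Peak("chr1", int(s), int(s) + 400) for s in starts]
        atac = CountMatrix(
            sp.csr_matrix(rng.poisson(3.0, size=(n_peaks, n_cells))),
            [f"p{i}" for i in range(n_peaks)],
            [f"c{i}" for i in range(n_cells)],
        )
        genes = []
        for g in range(n_genes):
            start = int(rng.integers(0, 45_000))
            end = start + int(rng.integers(500, 8000))
            strand = "+" if g % 2 == 0 else "-"
            tss = start if strand == "+" else end - 1
            genes.append(GeneAnnotation(f"G{g}", "chr1", strand, tss, start, end))
        upstream = 1500
        act = gene_activity_scores(atac, peaks, genes, upstream_bp=upstream)
        dense = atac.values.toarray()
        for gi, gene in enumerate(genes):
            if gene.strand == "+":
                ws, we = gene.start - upstream, gene.end
            else:
                ws, we = gene.start, gene.end + upstream
            expected = sum(
                dense[pi]
                for pi, p in enumerate(peaks)
                if p.start < we and p.end > max(ws, 0)
            )
            expected = expected if not np.isscalar(expected) else np.zeros(n_cells)
            np.testing.assert_array_equal(act.values.toarray()[gi], expected)

    def test_gene_on_missing_chromosome_gets_zero_row(self):
        atac, peaks, gene = self._setup()
        far = GeneAnnotation("G2", "chrX", "+", 100)
        act = gene_activity_scores(atac, peaks, [gene, far], upstream_bp=0)
        assert act.values.toarray()[1].sum() == 0


class TestJointEmbedding:
    def test_identical_matrices_make_counterparts_mutual_nn(self):
        rng = np.random.default_rng(0)
        counts = _counts(rng, 60, 25)
        emb_r, emb_a = joint_embedding(counts, counts, n_dims=5, n_features=60)
        d = cdist(emb_r.coords, emb_a.coords)
        assert (d.argmin(axis=1) == np.arange(25)).all()

    def test_cell_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        rna = _counts(rng, 50, 20)
        act = _counts(rng, 50, 18)
        emb_r, _ = joint_embedding(rna, act, n_dims=4, n_features=50)
        perm = rng.permutation(20)
        rna_p = CountMatrix(
            rna.values[:, perm], list(rna.feature_ids), [rna.cell_ids[i] for i in perm]
        )
        emb_rp, _ = joint_embedding(rna_p, act, n_dims=4, n_features=50)
        np.testing.assert_allclose(emb_rp.coords, emb_r.coords[perm], atol=1e-8)

    def test_cluster_structure_preserved(self):
        # two planted clusters: silhouette in the co-embedding is positive
        rng = np.random.default_rng(2)
        n_feat, n_cells = 80, 60
        base = rng.gamma(2.0, 1.0, size=(n_feat, 1))
        shift = np.zeros((n_feat, 1))
        shift[: n_feat // 2] = 3.0
        labels = np.array([0] * (n_cells // 2) + [1] * (n_cells // 2))
        lam = base + shift * labels[None, :]
        rna = CountMatrix(sp.csr_matrix(rng.poisson(lam)), [f"g{i}" for i in range(n_feat)],
                          [f"r{i}" for i in range(n_cells)])
        act = CountMatrix(sp.csr_matrix(rng.poisson(lam)), [f"g{i}" for i in range(n_feat)],
                          [f"a{i}" for i in range(n_cells)])
        emb_r, emb_a = joint_embedding(rna, act, n_dims=5, n_features=80)
        coords = np.vstack([emb_r.coords, emb_a.coords])
        assert silhouette_score(coords, np.tile(labels, 2)) > 0

    def test_too_few_shared_features_raises(self):
        rng = np.random.default_rng(3)
        rna = _counts(rng, 4, 10, prefix="x")
        act = _counts(rng, 4, 10, prefix="x")
        with pytest.raises(ValueError, match="shared features"):
            joint_embedding(rna, act, n_dims=10, n_features=4)


class TestPairCells:
    def _emb(self, coords, modality, prefix):
        ids = [f"{prefix}{i}" for i in range(len(coords))]
        return Embedding(np.asarray(coords, float), ids, modality)

    def test_trivial_two_by_two(self):
        emb_r = self._emb([[0, 0], [5, 0]], "RNA", "r")
        emb_a = self._emb([[0, 0], [5, 0]], "ATAC", "a")
        pairing = pair_cells(emb_r, emb_a, k_candidates=2)
        assert set(pairing.pairs) == {("r0", "a0"), ("r1", "a1")}
        assert pairing.total_cost == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_minimum_on_6x6(self, seed):
        rng = np.random.default_rng(seed)
        emb_r = self._emb(rng.normal(size=(6, 4)), "RNA", "r")
        emb_a = self._emb(rng.normal(size=(6, 4)), "ATAC", "a")
        pairing = pair_cells(emb_r, emb_a, k_candidates=6)
        d = cdist(emb_r.coords, emb_a.coords)
        best = min(
            sum(d[i, p[i]] for i in range(6)) for p in itertools.permutations(range(6))
        )
        assert pairing.total_cost == pytest.approx(best, abs=1e-10)

    def test_beats_random_permutations(self):
        rng = np.random.default_rng(7)
        emb_r = self._emb(rng.normal(size=(40, 6)), "RNA", "r")
        emb_a = self._emb(rng.normal(size=(40, 6)), "ATAC", "a")
        pairing = pair_cells(emb_r, emb_a, k_candidates=10)
        d = cdist(emb_r.coords, emb_a.coords)
        for _ in range(1000):
            perm = rng.permutation(40)
            assert pairing.total_cost <= d[np.arange(40), perm].sum() + 1e-9

    def test_one_to_one_on_rectangular_input(self):
        rng = np.random.default_rng(8)
        emb_r = self._emb(rng.normal(size=(12, 3)), "RNA", "r")
        emb_a = self._emb(rng.normal(size=(9, 3)), "ATAC", "a")
        pairing = pair_cells(emb_r, emb_a, k_candidates=4)
        assert len(pairing.pairs) == 9
        assert len(pairing.unmatched_rna) == 3
        assert len({r for r, _ in pairing.pairs}) == 9
        assert len({a for _, a in pairing.pairs}) == 9


class TestEvaluatePairing:
    def _pairing(self, pairs):
        from scegrn.integration import Pairing

        return Pairing(pairs=pairs, costs=np.zeros(len(pairs)), total_cost=0.0)

    def test_perfect_pairing_scores_one(self):
        pairs = [(f"r{i}", f"a{i}") for i in range(8)]
        labels = {f"r{i}": f"k{i % 2}" for i in range(8)}
        labels.update({f"a{i}": f"k{i % 2}" for i in range(8)})
        res = evaluate_pairing(self._pairing(pairs), pairs, labels)
        assert res == {"exact_pair_recovery": 8.0, "celltype_accuracy": 1.0}

    def test_all_cross_cluster_scores_zero(self):
        pairs = [("r0", "a1"), ("r1", "a0")]
        labels = {"r0": "x", "r1": "y", "a0": "x", "a1": "y"}
        truth = [("r0", "a0"), ("r1", "a1")]
        res = evaluate_pairing(self._pairing(pairs), truth, labels)
        assert res == {"exact_pair_recovery": 0.0, "celltype_accuracy": 0.0}

    def test_random_pairing_on_balanced_clusters_near_quarter(self):
        # uniform random matching over 4 balanced clusters: expectation 0.25
        rng = np.random.default_rng(9)
        n = 800
        labels = {}
        for i in range(n):
            labels[f"r{i}"] = labels[f"a{i}"] = f"k{i % 4}"
        accs = []
        for _ in range(5):
            perm = rng.permutation(n)
            pairs = [(f"r{i}", f"a{perm[i]}") for i in range(n)]
            accs.append(
                evaluate_pairing(self._pairing(pairs), [], labels)["celltype_accuracy"]
            )
        assert np.mean(accs) == pytest.approx(0.25, abs=0.05)
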