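"""Quantitative GRN, enhancer filtering, eGRN assembly and network statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from conftest import brute_betweenness
from scegrn.grn import (
    EGRN,
    QuantGRN,
    assemble_egrn,
    enhancer_links,
    network_statistics,
    quantitative_grn,
    tf_peak_time,
)
from scegrn.io import EdgeRecord, MotifMatches
from scegrn.linking import PeakGeneLink
from scegrn.trajectory import BinnedMatrix


def _binned(values, ids):
    values = np.asarray(values, float)
    return BinnedMatrix(values, np.arange(values.shape[1], dtype=float) + 0.5, ids)


class TestQuantitativeGRN:
    def test_identical_profiles_give_one(self):
        prof = np.sin(np.linspace(0, 3, 25))
        q = quantitative_grn(_binned(prof[None], ["T"]), _binned(prof[None], ["G"]), ["T"], ["G"])
        assert q.r_matrix.at["T", "G"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_pearson(self, seed):
        rng = np.random.default_rng(seed)
        act = rng.normal(size=(5, 30))
        expr = rng.normal(size=(7, 30))
        tfs = [f"T{i}" for i in range(5)]
        genes = [f"G{i}" for i in range(7)]
        q = quantitative_grn(_binned(act, tfs), _binned(expr, genes), tfs, genes)
        for i, tf in enumerate(tfs):
            for j, g in enumerate(genes):
                ref = np.corrcoef(act[i], expr[j])[0, 1]
                assert q.r_matrix.at[tf, g] == pytest.approx(ref, abs=1e-10)

    def test_bin_permutation_invariance(self):
        rng = np.random.default_rng(5)
        act = rng.normal(size=(3, 20))
        expr = rng.normal(size=(4, 20))
        tfs, genes = list("ABC"), list("wxyz")
        q1 = quantitative_grn(_binned(act, tfs), _binned(expr, genes), tfs, genes)
        perm = rng.permutation(20)
        q2 = quantitative_grn(_binned(act[:, perm], tfs), _binned(expr[:, perm], genes), tfs, genes)
        np.testing.assert_allclose(q1.r_matrix.values, q2.r_matrix.values, atol=1e-12)

    def test_constant_profile_flagged_nan(self):
        act = np.vstack([np.ones(10)])
        expr = np.linspace(0, 1, 10)[None]
        q = quantitative_grn(_binned(act, ["T"]), _binned(expr, ["G"]), ["T"], ["G"])
        assert np.isnan(q.r_matrix.at["T", "G"])


class TestEnhancerFilter:
    @pytest.mark.parametrize(
        ("distance", "kept"), [(1999, False), (2000, True), (2001, True)]
    )
    def test_2kb_boundary(self, distance, kept):
        link = PeakGeneLink(0, "G", 0.8, distance)
        out = enhancer_links([link], min_tss_distance=2000)
        assert (len(out) == 1) == kept
        if kept:
            assert out[0].is_enhancer

    def test_zero_threshold_keeps_all(self):
        links = [PeakGeneLink(i, "G", 0.8, d) for i, d in enumerate([0, 1, 5000])]
        assert len(enhancer_links(links, min_tss_distance=0)) == 3


def _random_instance(rng, n_tfs=6, n_genes=12, n_peaks=25):
    tfs = [f"T{i}" for i in range(n_tfs)]
    genes = [f"G{i}" for i in range(n_genes)]
    r = rng.uniform(-1, 1, size=(n_tfs, n_genes))
    qgrn = QuantGRN(pd.DataFrame(r, index=tfs, columns=genes))
    motif = (rng.random((n_peaks, n_tfs)) < 0.3).astype(int)
    motifs = MotifMatches(sp.csc_matrix(motif), tfs, {t: f"g{t}" for t in tfs})
    links = []
    for _ in range(30):
        links.append(
            PeakGeneLink(
                int(rng.integers(0, n_peaks)),
                genes[int(rng.integers(0, n_genes))],
                float(rng.uniform(0.5, 1)),
                int(rng.integers(0, 10_000)),
            )
        )
    return qgrn, motifs, links, motif


class TestAssembleEGRN:
    def test_motif_absent_blocks_edge(self):
        qgrn = QuantGRN(pd.DataFrame([[0.9]], index=["T"], columns=["G"]))
        motifs = MotifMatches(sp.csc_matrix(np.array([[0], [1]])), ["T"], {"T": "gT"})
        links = [PeakGeneLink(0, "G", 0.9, 5000, True)]  # enhancer lacks the motif
        egrn = assemble_egrn(qgrn, links, motifs, weight_cutoff=0.4)
        assert egrn.edges == []

    def test_all_rules_met_creates_weighted_edge(self):
        qgrn = QuantGRN(pd.DataFrame([[0.9]], index=["T"], columns=["G"]))
        motifs = MotifMatches(sp.csc_matrix(np.array([[1], [0]])), ["T"], {"T": "gT"})
        links = [PeakGeneLink(0, "G", 0.9, 5000, True)]
        egrn = assemble_egrn(qgrn, links, motifs, weight_cutoff=0.4)
        assert egrn.edges == [EdgeRecord("T", "G", 0.9)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_rule_check(self, seed):
        rng = np.random.default_rng(seed)
        qgrn, motifs, links, motif = _random_instance(rng)
        cutoff, min_d = 0.4, 2000
        enh = enhancer_links(links, min_d)
        egrn = assemble_egrn(qgrn, enh, motifs, weight_cutoff=cutoff)

        expected = set()
        for tf in qgrn.r_matrix.index:
            k = motifs.tf_ids.index(tf)
            for gene in qgrn.r_matrix.columns:
                w = qgrn.r_matrix.at[tf, gene]
                if w < cutoff:
                    continue
                mediated = any(
                    l.gene_id == gene and l.tss_distance >= min_d and motif[l.peak_index, k]
                    for l in links
                )
                if mediated:
                    expected.add((tf, gene))
        assert egrn.edge_set == expected

    def test_egrn_subset_of_quantitative_network(self):
        rng = np.random.default_rng(11)
        qgrn, motifs, links, _ = _random_instance(rng)
        egrn = assemble_egrn(qgrn, enhancer_links(links), motifs, weight_cutoff=0.4)
        quant_edges = {
            (tf, g)
            for tf in qgrn.r_matrix.index
            for g in qgrn.r_matrix.columns
            if qgrn.r_matrix.at[tf, g] >= 0.4
        }
        assert egrn.edge_set <= quant_edges

    def test_empty_result_warns_not_raises(self):
        qgrn = QuantGRN(pd.DataFrame([[0.1]], index=["T"], columns=["G"]))
        motifs = MotifMatches(sp.csc_matrix(np.array([[1]])), ["T"], {"T": "gT"})
        with pytest.warns(UserWarning, match="empty"):
            egrn = assemble_egrn(qgrn, [], motifs)
        assert egrn.edges == []


class TestNetworkStatistics:
    def test_single_isolated_node(self):
        stats = network_statistics(EGRN(edges=[]), nodes=["T"])
        assert stats.loc["T", "pagerank"] == pytest.approx(1.0, abs=1e-9)
        assert stats.loc["T", "betweenness"] == 0.0

    def test_pagerank_sums_to_one_on_edge_graph(self):
        egrn = EGRN(edges=[EdgeRecord("T", "G", 0.5), EdgeRecord("T", "H", 0.7)])
        stats = network_statistics(egrn)
        assert stats["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_node_cycle_symmetric_pagerank(self):
        egrn = EGRN(edges=[EdgeRecord("A", "B", 0.9), EdgeRecord("B", "A", 0.9)])
        stats = network_statistics(egrn)
        assert stats.loc["A", "pagerank"] == pytest.approx(0.5, abs=1e-9)
        assert stats.loc["B", "pagerank"] == pytest.approx(0.5, abs=1e-9)

    def test_pagerank_matches_power_iteration(self):
        # independent dense power iteration on the documented transition model
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(6)]
        edges = [
            EdgeRecord(nodes[i], nodes[j], float(rng.uniform(-1, 1)))
            for i in range(6)
            for j in range(6)
            if i != j and rng.random() < 0.4
        ]
        stats = network_statistics(EGRN(edges=edges), damping=0.85)
        present = sorted({e.tf for e in edges} | {e.gene for e in edges})
        n = len(present)
        w = np.zeros((n, n))
        idx = {v: i for i, v in enumerate(present)}
        for e in edges:
            w[idx[e.tf], idx[e.gene]] += abs(e.weight)
        p = np.full(n, 1 / n)
        for _ in range(10_000):
            out = w.sum(axis=1)
            flow = np.zeros(n)
            for i in range(n):
                if out[i] > 0:
                    flow += p[i] * w[i] / out[i]
                else:
                    flow += p[i] / n  # dangling: uniform teleport
            new = (1 - 0.85) / n + 0.85 * flow
            if np.abs(new - p).sum() < 1e-13:
                p = new
                break
            p = new
        for v in present:
            assert stats.loc[v, "pagerank"] == pytest.approx(p[idx[v]], abs=1e-8)

    @pytest.mark.parametrize("seed", range(6))
    def test_betweenness_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        nodes = [f"n{i}" for i in range(n)]
        edges = [
            EdgeRecord(nodes[i], nodes[j], 0.5)
            for i in range(n)
            for j in range(n)
            if i != j and rng.random() < 0.35
        ]
        if not edges:
            return
        stats = network_statistics(EGRN(edges=edges))
        ref = brute_betweenness([(e.tf, e.gene) for e in edges], sorted(stats.index))
        for v in stats.index:
            assert stats.loc[v, "betweenness"] == pytest.approx(ref[v], abs=1e-9)


class TestTFPeakTime:
    def test_peaked_profile(self):
        vals = np.zeros((1, 100))
        vals[0, 37] = 5.0
        binned = _binned(vals, ["T"])
        times, flat = tf_peak_time(binned)
        assert times["T"] == pytest.approx(37.5)
        assert flat == []

    def test_monotone_profile_peaks_at_last_bin(self):
        binned = _binned(np.linspace(0, 1, 50)[None], ["T"])
        times, _ = tf_peak_time(binned)
        assert times["T"] == pytest.approx(binned.bin_centers[-1])

    def test_flat_profile_flagged_earliest(self):
        binned = _binned(np.ones((1, 20)), ["T"])
        times, flat = tf_peak_time(binned)
        assert times["T"] == pytest.approx(binned.bin_centers[0])
        assert flat == ["T"]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_argmax_scan(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(6, 40))
        ids = [f"T{i}" for i in range(6)]
        binned = _binned(vals, ids)
        times, _ = tf_peak_time(binned)
        for i, tf in enumerate(ids):
            best = min(range(40), key=lambda b: (-vals[i, b], b))
            assert times[tf] == pytest.approx(binned.bin_centers[best])
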