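"""Quantitative GRN, enhancer constraint, eGRN assembly and regulator statistics.

The quantitative network is the matrix of Pearson correlations between each
selected TF's activity profile and each selected gene's expression profile
over trajectory bins. Independently, peak-to-gene links are restricted to
enhancers — peaks at least 2 kb from the target's TSS — and a TF is accepted
as a regulator of a gene only if the gene has at least one linked enhancer
carrying that TF's motif. The final eGRN keeps TF-gene pairs present in both
networks, weighted by the correlation.

Regulators are ranked by PageRank (influence through outgoing regulation,
computed on |weight|) and betweenness (bridging position between network
modules, computed on unweighted shortest paths). Each TF node also carries
the pseudotime at which its smoothed activity peaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from scegrn._stats import pearson_matrix
from scegrn.io import EdgeRecord, MotifMatches
from scegrn.linking import PeakGeneLink
from scegrn.trajectory import BinnedMatrix

logger = logging.getLogger(__name__)


@dataclass
class QuantGRN:
    """Dense TF-activity x gene-expression correlation matrix over bins."""

    r_matrix: pd.DataFrame  # rows: TF ids, columns: gene ids; NaN = undefined

    def __post_init__(self) -> None:
        vals = self.r_matrix.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and np.abs(finite).max() > 1 + 1e-9:
            raise ValueError("correlations outside [-1, 1]")


@dataclass
class EGRN:
    """Directed TF -> gene network with per-node centralities and peak times."""

    edges: list[EdgeRecord]
    node_stats: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["pagerank", "betweenness", "peak_time"]
        )
    )

    def to_graph(self) -> nx.DiGraph:
        graph = nx.DiGraph()
        for node in self.node_stats.index:
            graph.add_node(str(node))
        for e in self.edges:
            graph.add_edge(e.tf, e.gene, weight=float(e.weight))
        return graph

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.tf, e.gene) for e in self.edges}


def quantitative_grn(
    activity_binned: BinnedMatrix,
    expression_binned: BinnedMatrix,
    selected_tfs: list[str],
    selected_genes: list[str],
) -> QuantGRN:
    """Correlate every selected TF's activity with every selected gene's expression.

    Entries where either profile is constant over bins are NaN (undefined
    correlation) and never become edges.
    """
    if not selected_tfs or not selected_genes:
        raise ValueError("TF and gene selections must be non-empty")
    act = activity_binned.subset(selected_tfs).values
    expr = expression_binned.subset(selected_genes).values
    r = pearson_matrix(act, expr)
    return QuantGRN(pd.DataFrame(r, index=selected_tfs, columns=selected_genes))


def enhancer_links(
    links: list[PeakGeneLink], min_tss_distance: int = 2000
) -> list[PeakGeneLink]:
    """Keep links whose peak is at least ``min_tss_distance`` bp from the TSS
    (the enhancer definition; the boundary value itself is kept)."""
    return [
        PeakGeneLink(l.peak_index, l.gene_id, l.correlation, l.tss_distance, True)
        for l in links
        if l.tss_distance >= min_tss_distance
    ]


def assemble_egrn(
    qgrn: QuantGRN,
    enh_links: list[PeakGeneLink],
    motifs: MotifMatches,
    weight_cutoff: float = 0.4,
    mode: str = "positive",
) -> EGRN:
    """Intersect the quantitative GRN with the enhancer-mediated network.

    An edge TF -> gene is kept iff (1) the activity-expression correlation
    passes ``weight_cutoff`` (signed in ``positive`` mode, |r| in ``absolute``
    mode), (2) the gene has at least one enhancer link, and (3) the TF's
    motif matches at least one of the gene's linked enhancer peaks. Edge
    weight is the correlation. TF self-edges (a factor regulating its own
    coding gene) are permitted and flagged.
    """
    if mode not in ("positive", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    gene_enhancers: dict[str, set[int]] = {}
    for l in enh_links:
        gene_enhancers.setdefault(l.gene_id, set()).add(l.peak_index)

    motif_csc = motifs.indicator.tocsc()
    tf_index = {t: i for i, t in enumerate(motifs.tf_ids)}
    tf_peaks: dict[str, set[int]] = {}

    edges: list[EdgeRecord] = []
    r = qgrn.r_matrix
    for tf in r.index:
        ti = tf_index.get(tf)
        if ti is None:
            continue
        if tf not in tf_peaks:
            tf_peaks[tf] = set(motif_csc[:, ti].indices.tolist())
        bound = tf_peaks[tf]
        coding_gene = motifs.tf_to_gene.get(tf)
        for gene in r.columns:
            w = r.at[tf, gene]
            if not np.isfinite(w):
                continue
            passes = (abs(w) >= weight_cutoff) if mode == "absolute" else (w >= weight_cutoff)
            if not passes:
                continue
            enh = gene_enhancers.get(gene)
            if not enh or not (enh & bound):
                continue
            edges.append(EdgeRecord(tf, gene, float(w), self_edge=(gene == coding_gene)))
    if not edges:
        warnings.warn("assembled eGRN is empty", stacklevel=2)
    return EGRN(edges)


def network_statistics(
    egrn: EGRN, damping: float = 0.85, nodes: list[str] | None = None
) -> pd.DataFrame:
    """PageRank (on |weight|) and betweenness (unweighted) for every node.

    PageRank treats the eGRN as a directed graph with row-normalized |w|
    transition weights and uniform teleport for dangling nodes, iterated to
    an L1 change below 1e-10; it sums to 1. Betweenness counts unweighted
    directed shortest paths, unnormalized — correlation weights carry no
    path-length interpretation. ``nodes`` adds isolated nodes beyond those
    incident to an edge.
    """
    graph = nx.DiGraph()
    node_set = {e.tf for e in egrn.edges} | {e.gene for e in egrn.edges}
    if nodes:
        node_set |= set(nodes)
    graph.add_nodes_from(sorted(node_set))
    for e in egrn.edges:
        graph.add_edge(e.tf, e.gene, absweight=abs(e.weight))
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(columns=["pagerank", "betweenness"])
    pr = nx.pagerank(
        graph,
        alpha=damping,
        weight="absweight",
        tol=1e-10 / graph.number_of_nodes(),
        max_iter=1000,
    )
    btw = nx.betweenness_centrality(graph, normalized=False)
    return pd.DataFrame({"pagerank": pd.Series(pr), "betweenness": pd.Series(btw)})


def tf_peak_time(
    activity_binned: BinnedMatrix, tf_ids: list[str] | None = None
) -> tuple[dict[str, float], list[str]]:
    """Pseudotime of maximal smoothed activity per TF (bin center).

    Ties break to the earliest bin. Returns the map and a list of TFs whose
    profile is flat (their peak time defaults to the first bin center).
    """
    wanted = tf_ids if tf_ids is not None else activity_binned.feature_ids
    sub = activity_binned.subset(wanted)
    idx = np.argmax(sub.values, axis=1)  # argmax returns the first maximum
    flat = [
        tf
        for tf, row in zip(wanted, sub.values)
        if np.ptp(row[np.isfinite(row)]) == 0
    ]
    times = {tf: float(sub.bin_centers[i]) for tf, i in zip(wanted, idx)}
    return times, flat


def annotate_nodes(
    egrn: EGRN,
    stats: pd.DataFrame,
    peak_times: dict[str, float],
) -> pd.DataFrame:
    """Join centralities and TF peak times into the eGRN's node table."""
    node_stats = stats.copy()
    node_stats["peak_time"] = [peak_times.get(n, np.nan) for n in node_stats.index]
    egrn.node_stats = node_stats
    return node_stats
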