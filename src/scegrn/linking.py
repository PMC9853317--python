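"""Trajectory-conditioned selection of candidate TFs and genes, and peak-to-gene links.

A TF is a candidate regulator when its motif-deviation activity profile and
the expression profile of its coding gene correlate along the trajectory: a
high correlation means the factor is both expressed and its motif is
differentially accessible, which disambiguates family members sharing a
motif. Candidate target genes are the most variable genes along the
trajectory (top fraction, default 10%). Peaks are linked to genes within a
genomic distance window of the TSS when peak accessibility and gene
expression correlate over trajectory bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scegrn._stats import pearson_rows
from scegrn.io import GeneAnnotation, MotifMatches, Peak, tss_distance
from scegrn.trajectory import BinnedMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TFSelection:
    """Activity-expression correlation and selection flag for one TF."""

    tf_id: str
    correlation: float
    selected: bool


@dataclass(frozen=True)
class PeakGeneLink:
    """A peak whose accessibility tracks a gene's expression along the trajectory."""

    peak_index: int
    gene_id: str
    correlation: float
    tss_distance: int
    is_enhancer: bool = False

    def __post_init__(self) -> None:
        if self.tss_distance < 0:
            raise ValueError("tss_distance must be >= 0")


def links_to_frame(links: list[PeakGeneLink], peaks: list[Peak] | None = None) -> pd.DataFrame:
    rows = []
    for l in links:
        row = {
            "peak_index": l.peak_index,
            "gene_id": l.gene_id,
            "correlation": l.correlation,
            "tss_distance": l.tss_distance,
            "is_enhancer": l.is_enhancer,
        }
        if peaks is not None:
            p = peaks[l.peak_index]
            row.update({"chrom": p.chrom, "start": p.start, "end": p.end})
        rows.append(row)
    cols = ["peak_index", "gene_id", "correlation", "tss_distance", "is_enhancer"]
    if peaks is not None:
        cols = ["chrom", "start", "end"] + cols
    return pd.DataFrame(rows, columns=cols)


def select_tfs(
    activity_binned: BinnedMatrix,
    expression_binned: BinnedMatrix,
    motifs: MotifMatches,
    cor_cutoff: float = 0.4,
    mode: str = "positive",
) -> list[TFSelection]:
    """Select TFs whose binned activity correlates with their gene's expression.

    ``mode='positive'`` (default) keeps TFs with r >= cutoff — the reading
    that a driver is both more expressed and more accessible; ``mode='absolute'``
    keeps |r| >= cutoff to admit repressors. TFs whose coding gene is absent
    from the expression matrix are skipped with a logged reason.
    """
    if mode not in ("positive", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    expr_index = {g: i for i, g in enumerate(expression_binned.feature_ids)}
    out: list[TFSelection] = []
    for tf in activity_binned.feature_ids:
        gene = motifs.tf_to_gene.get(tf)
        if gene is None or gene not in expr_index:
            logger.info("TF %s skipped: coding gene %r not in expression matrix", tf, gene)
            continue
        act = activity_binned.row(tf)
        expr = expression_binned.values[expr_index[gene]]
        r = float(pearson_rows(act, expr)[0])
        if math.isnan(r):
            out.append(TFSelection(tf, float("nan"), False))
            continue
        selected = (abs(r) >= cor_cutoff) if mode == "absolute" else (r >= cor_cutoff)
        out.append(TFSelection(tf, r, selected))
    return out


def select_variable_genes(
    expression_binned: BinnedMatrix, top_fraction: float = 0.1
) -> list[str]:
    """Return the ceil(top_fraction * n_genes) genes most variable along the
    trajectory, measured as the variance of the smoothed binned profile.
    Ties break lexicographically by gene id for determinism."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    n = len(expression_binned.feature_ids)
    k = math.ceil(top_fraction * n)
    variances = expression_binned.values.var(axis=1)
    order = sorted(
        range(n), key=lambda i: (-variances[i], expression_binned.feature_ids[i])
    )
    return [expression_binned.feature_ids[i] for i in order[:k]]


def peak_gene_links(
    atac_binned: BinnedMatrix,
    expression_binned: BinnedMatrix,
    peaks: list[Peak],
    genes: list[GeneAnnotation],
    gene_ids: list[str] | None = None,
    max_distance: int = 250_000,
    cor_cutoff: float = 0.5,
) -> list[PeakGeneLink]:
    """Link peaks to genes by correlation along the trajectory.

    Candidate pairs are (peak, gene) with TSS distance (nearest peak edge,
    0 when the peak covers the TSS) at most ``max_distance``; a link is kept
    when the Pearson correlation of the peak's binned accessibility and the
    gene's binned expression is >= ``cor_cutoff``. ``gene_ids`` restricts the
    genes considered (e.g. to the selected variable genes).
    """
    if len(peaks) != len(atac_binned.feature_ids):
        raise ValueError("peaks must align with binned ATAC rows")
    expr_index = {g: i for i, g in enumerate(expression_binned.feature_ids)}
    gene_map = {g.gene_id: g for g in genes}
    wanted = gene_ids if gene_ids is not None else list(gene_map)

    peak_chroms = np.array([p.chrom for p in peaks])
    peak_starts = np.array([p.start for p in peaks])
    peak_ends = np.array([p.end for p in peaks])

    n_bins = atac_binned.values.shape[1]
    az = atac_binned.values - atac_binned.values.mean(axis=1, keepdims=True)
    a_sd = az.std(axis=1)
    ez = expression_binned.values - expression_binned.values.mean(axis=1, keepdims=True)
    e_sd = ez.std(axis=1)

    links: list[PeakGeneLink] = []
    for gid in wanted:
        gene = gene_map.get(gid)
        if gene is None or gid not in expr_index:
            continue
        on_chrom = np.flatnonzero(peak_chroms == gene.chrom)
        if on_chrom.size == 0:
            continue
        dists = np.array(
            [tss_distance(peak_starts[i], peak_ends[i], gene.tss) for i in on_chrom]
        )
        cand = on_chrom[dists <= max_distance]
        cand_d = dists[dists <= max_distance]
        if cand.size == 0:
            continue
        gi = expr_index[gid]
        if e_sd[gi] == 0:
            continue
        denom = a_sd[cand] * e_sd[gi] * n_bins
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (az[cand] @ ez[gi]) / denom
        for pi, d, rv in zip(cand, cand_d, r):
            if np.isfinite(rv) and rv >= cor_cutoff:
                links.append(PeakGeneLink(int(pi), gid, float(rv), int(d)))
    return links
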