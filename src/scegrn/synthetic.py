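"""Synthetic multiome simulator with a planted enhancer-based regulatory network.

The simulator emulates a differentiation-like process on a single linear
synthetic chromosome so that every pipeline stage has exact ground truth:

* each cell carries a true pseudotime t ~ Uniform(0, 100) and a cluster
  label from the t quartile (four ordered clusters C1..C4);
* each driver TF has a smooth latent activity profile f_k(t) — a logistic
  ramp (up or down) or a Gaussian bump — and its coding gene's expression
  rate follows softplus(f_k(t)) plus Gaussian noise;
* each target gene's rate follows softplus(sum_k w_kg f_k(t)) with nonzero
  weights only on planted TF -> gene edges; decoy genes and decoy TFs have
  pseudotime-independent rates;
* every gene gets one promoter peak (covering the TSS, hence failing the
  2 kb enhancer rule by construction) and a configurable number of enhancer
  peaks 2-100 kb away whose accessibility rate tracks the gene's expression
  rate; promoter, decoy-gene and intergenic decoy peaks are flat in t;
* the motif matrix marks TF k in the enhancers of gene g iff k -> g is
  planted, plus a small false-match rate sprinkled over all peaks;
* counts are Poisson (negative-binomial optionally) around depth-scaled
  rates with per-cell lognormal depth factors.

Genes are spaced widely enough (default 500 kb) that one gene's enhancers
never fall inside a neighbor's linking window: the planted peak-to-gene truth
is then unambiguous, which is what makes recall/precision well defined.

All randomness flows from one seed; a fixed seed gives bit-identical output.
``SimulatedMultiome.as_unpaired`` relabels the same counts into separate RNA
and ATAC cell copies (ATAC columns shuffled) so paired and unpaired analyses
of one simulation are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from scegrn import io

_SOFTPLUS_CAP = 30.0


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.where(x > _SOFTPLUS_CAP, x, np.log1p(np.exp(np.minimum(x, _SOFTPLUS_CAP))))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic multiome.

    Defaults describe a 2,000-cell differentiation with 10 driver TFs, 200
    planted target genes and as many flat decoys, two enhancers per gene at
    2-100 kb from the TSS, and moderate rate noise. ``edge_density`` is the
    probability that any (TF, target) pair is a planted edge.
    """

    n_cells: int = 2000
    n_tfs: int = 10
    n_decoy_tfs: int = 10
    n_target_genes: int = 200
    n_decoy_genes: int = 200
    enhancers_per_gene: int = 2
    promoter_per_gene: int = 1
    n_decoy_peaks: int = 200
    gene_length: int = 20_000
    tss_spacing: int = 500_000
    enhancer_distance_range: tuple[int, int] = (2_000, 100_000)
    peak_width: int = 500
    depth_rna: float = 5_000.0
    depth_atac: float = 5_000.0
    noise_sd: float = 0.2
    edge_density: float = 0.15
    motif_false_match_rate: float = 0.01
    repressive_fraction: float = 0.0
    nb_dispersion: float | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        positive = {
            "n_cells": self.n_cells,
            "n_tfs": self.n_tfs,
            "n_target_genes": self.n_target_genes,
            "enhancers_per_gene": self.enhancers_per_gene,
            "promoter_per_gene": self.promoter_per_gene,
            "gene_length": self.gene_length,
            "tss_spacing": self.tss_spacing,
            "peak_width": self.peak_width,
            "depth_rna": self.depth_rna,
            "depth_atac": self.depth_atac,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive (got {value})")
        for name, value in {
            "n_decoy_tfs": self.n_decoy_tfs,
            "n_decoy_genes": self.n_decoy_genes,
            "n_decoy_peaks": self.n_decoy_peaks,
            "noise_sd": self.noise_sd,
        }.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative (got {value})")
        lo, hi = self.enhancer_distance_range
        if lo < 2_000:
            raise ValueError(
                "enhancer_distance_range minimum must be >= 2000 bp so planted "
                "links survive the enhancer filter"
            )
        if hi <= lo:
            raise ValueError("enhancer_distance_range must be increasing")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if not 0 <= self.motif_false_match_rate < 1:
            raise ValueError("motif_false_match_rate must be in [0, 1)")
        if not 0 <= self.repressive_fraction <= 1:
            raise ValueError("repressive_fraction must be in [0, 1]")
        if self.promoter_per_gene != 1:
            raise ValueError("exactly one promoter peak per gene is supported")


@dataclass
class GroundTruth:
    """Planted structure the pipeline is asked to recover."""

    planted_edges: pd.DataFrame  # tf, gene, weight
    planted_links: pd.DataFrame  # peak_index, gene_id, tss_distance, is_dynamic
    true_pseudotime: pd.Series  # indexed by cell id
    cluster_labels: pd.Series  # indexed by cell id
    true_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.planted_edges["tf"], self.planted_edges["gene"]))


@dataclass
class SimulatedMultiome:
    """One simulated dataset: matrices, annotations, motifs, metadata, truth."""

    rna: io.CountMatrix
    atac: io.CountMatrix
    peaks: list[io.Peak]
    genes: list[io.GeneAnnotation]
    motifs: io.MotifMatches
    cells: pd.DataFrame
    truth: GroundTruth
    config: SimConfig

    def as_unpaired(self) -> "SimulatedMultiome":
        """Split into RNA-only and ATAC-only cell copies with shuffled ATAC order.

        The count matrices are the same draws as the paired dataset — only the
        cell labels change — so downstream results of a perfectly paired
        analysis and an unpaired analysis fed the true pairs coincide exactly.
        """
        rng = np.random.default_rng(self.config.seed + 10_007)
        base_ids = list(self.rna.cell_ids)
        rna_ids = [f"rna_{c}" for c in base_ids]
        atac_ids = [f"atac_{c}" for c in base_ids]
        order = rng.permutation(len(base_ids))
        atac_shuffled = io.CountMatrix(
            self.atac.values[:, order],
            list(self.atac.feature_ids),
            [atac_ids[i] for i in order],
        )
        rna = io.CountMatrix(self.rna.values, list(self.rna.feature_ids), rna_ids)
        labels = self.truth.cluster_labels
        cells = pd.DataFrame(
            {
                "cell_id": rna_ids + [atac_ids[i] for i in order],
                "modality": ["RNA"] * len(base_ids) + ["ATAC"] * len(base_ids),
                "cluster": [labels[c] for c in base_ids]
                + [labels[base_ids[i]] for i in order],
            }
        )
        pt = pd.concat(
            [
                self.truth.true_pseudotime.rename(index=lambda c: f"rna_{c}"),
                self.truth.true_pseudotime.rename(index=lambda c: f"atac_{c}"),
            ]
        )
        lab = pd.concat(
            [
                labels.rename(index=lambda c: f"rna_{c}"),
                labels.rename(index=lambda c: f"atac_{c}"),
            ]
        )
        truth = GroundTruth(
            planted_edges=self.truth.planted_edges.copy(),
            planted_links=self.truth.planted_links.copy(),
            true_pseudotime=pt,
            cluster_labels=lab,
            true_pairs=list(zip(rna_ids, atac_ids)),
        )
        return SimulatedMultiome(
            rna, atac_shuffled, self.peaks, self.genes, self.motifs, cells, truth, self.config
        )

    # ------------------------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        """Emit the full MTX/TSV/BED fixture set plus ground-truth tables."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_count_matrix(
            self.rna, out / "rna.mtx", out / "rna_features.tsv", out / "rna_barcodes.tsv"
        )
        io.write_count_matrix(
            self.atac, out / "atac.mtx", out / "atac_features.tsv", out / "atac_barcodes.tsv"
        )
        io.write_peaks_bed(self.peaks, out / "peaks.bed")
        io.write_gene_annotations(self.genes, out / "genes.tsv")
        io.write_motif_matches(self.motifs, out / "motifs.mtx", out / "motif_tfs.tsv")
        self.cells.to_csv(out / "cells.tsv", sep="\t", index=False)
        self.truth.planted_edges.to_csv(out / "truth_edges.tsv", sep="\t", index=False)
        self.truth.planted_links.to_csv(out / "truth_links.tsv", sep="\t", index=False)
        self.truth.true_pseudotime.rename("pseudotime").rename_axis("cell_id").to_csv(
            out / "truth_pseudotime.tsv", sep="\t"
        )
        if self.truth.true_pairs:
            pd.DataFrame(self.truth.true_pairs, columns=["rna_cell", "atac_cell"]).to_csv(
                out / "truth_pairs.tsv", sep="\t", index=False
            )


def _tf_profiles(n_tfs: int, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth latent activity profiles: logistic ramps or Gaussian bumps,
    rescaled to span roughly [-amp, amp]."""
    profiles = np.empty((n_tfs, t.size))
    for k in range(n_tfs):
        kind = rng.choice(("ramp", "bump"))
        mid = rng.uniform(20, 80)
        if kind == "ramp":
            scale = rng.uniform(5, 15)
            base = 1.0 / (1.0 + np.exp(-(t - mid) / scale))
            if rng.random() < 0.5:
                base = 1.0 - base
        else:
            width = rng.uniform(8, 20)
            base = np.exp(-((t - mid) ** 2) / (2 * width**2))
        amp = rng.uniform(1.5, 3.0)
        profiles[k] = amp * (2.0 * base - 1.0)
    return profiles


def _mass_balance(rates: np.ndarray, dynamic: np.ndarray) -> np.ndarray:
    """Rescale dynamic rows so their per-cell sum is constant (their mean).

    Keeps each flat row's expected share of the per-cell total constant along
    pseudotime, so flat features stay flat after depth normalization.
    """
    if not dynamic.any():
        return rates
    out = rates.copy()
    mass = rates[dynamic].sum(axis=0)
    budget = mass.mean()
    if budget > 0 and (mass > 0).all():
        out[dynamic] = rates[dynamic] * (budget / mass)
    return out


def _sample_counts(
    rates: np.ndarray, depth: float, rng: np.random.Generator, dispersion: float | None
) -> sp.csr_matrix:
    """Poisson (or gamma-Poisson) counts around depth-scaled rates with
    lognormal per-cell depth factors."""
    col_sums = rates.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    size_factors = rng.lognormal(mean=0.0, sigma=0.3, size=rates.shape[1])
    lam = rates / col_sums * depth * size_factors
    if dispersion is not None and dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, lam * dispersion)
    return sp.csr_matrix(rng.poisson(lam))


def simulate_multiome(config: SimConfig) -> SimulatedMultiome:
    """Generate one paired multiome dataset with planted ground truth."""
    rng = np.random.default_rng(config.seed)
    n_cells = config.n_cells
    noise = config.noise_sd

    # (1) true pseudotime and ordered quartile clusters
    t = rng.uniform(0.0, 100.0, size=n_cells)
    quartiles = np.quantile(t, [0.25, 0.5, 0.75])
    cluster_idx = np.searchsorted(quartiles, t, side="right")
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    clusters = pd.Series([f"C{i + 1}" for i in cluster_idx], index=cell_ids)

    # (2) driver TF profiles and TF-gene expression rates
    f = _tf_profiles(config.n_tfs, t, rng)
    tf_ids = [f"TF{k:02d}" for k in range(config.n_tfs)]
    decoy_tf_ids = [f"DTF{k:02d}" for k in range(config.n_decoy_tfs)]
    tf_gene_ids = [f"g{tf}" for tf in tf_ids]
    decoy_tf_gene_ids = [f"g{tf}" for tf in decoy_tf_ids]
    target_ids = [f"gTGT{i:03d}" for i in range(config.n_target_genes)]
    decoy_ids = [f"gDCY{i:03d}" for i in range(config.n_decoy_genes)]
    gene_ids = tf_gene_ids + decoy_tf_gene_ids + target_ids + decoy_ids
    n_genes = len(gene_ids)

    def _noisy(rate: np.ndarray) -> np.ndarray:
        return np.maximum(rate + rng.normal(0.0, noise, size=rate.shape), 1e-3)

    rates = np.empty((n_genes, n_cells))
    row = 0
    for k in range(config.n_tfs):
        rates[row] = _noisy(_softplus(f[k]))
        row += 1
    for _ in range(config.n_decoy_tfs):
        rates[row] = _noisy(np.full(n_cells, _softplus(np.array([rng.uniform(-1, 1)]))[0]))
        row += 1

    # (3) planted edges and target-gene rates
    edge_mask = rng.random((config.n_tfs, config.n_target_genes)) < config.edge_density
    weights = rng.uniform(0.5, 1.5, size=edge_mask.shape)
    signs = np.where(
        rng.random(edge_mask.shape) < config.repressive_fraction, -1.0, 1.0
    )
    w = np.where(edge_mask, weights * signs, 0.0)
    target_rows = row
    for g in range(config.n_target_genes):
        rates[row] = _noisy(_softplus(w[:, g] @ f))
        row += 1
    for _ in range(config.n_decoy_genes):
        rates[row] = _noisy(np.full(n_cells, _softplus(np.array([rng.uniform(-1, 1)]))[0]))
        row += 1
    dynamic_gene = np.zeros(n_genes, bool)
    dynamic_gene[: config.n_tfs] = True  # driver TF coding genes
    dynamic_gene[target_rows : target_rows + config.n_target_genes] = edge_mask.any(axis=0)

    # Mass-balance: rescale the dynamic genes so their summed rate is the
    # same in every cell. Depth normalization divides each gene by the cell
    # total, so without this step flat genes would inherit a pseudotime trend
    # from the moving dynamic mass — the generator's contract is that decoys
    # are trajectory-independent *after* normalization.
    rates = _mass_balance(rates, dynamic_gene)

    planted_edges = pd.DataFrame(
        [
            (tf_ids[k], target_ids[g], w[k, g])
            for k in range(config.n_tfs)
            for g in range(config.n_target_genes)
            if edge_mask[k, g]
        ],
        columns=["tf", "gene", "weight"],
    )

    # (4) genome layout: one linear chromosome, alternating strands
    chrom = "chrS"
    genes: list[io.GeneAnnotation] = []
    for i, gid in enumerate(gene_ids):
        tss = 200_000 + i * config.tss_spacing
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            start, end = tss, tss + config.gene_length
        else:
            start, end = tss - config.gene_length + 1, tss + 1
        genes.append(io.GeneAnnotation(gid, chrom, strand, tss, start, end))

    peaks: list[io.Peak] = []
    peak_rate_rows: list[np.ndarray] = []
    link_rows: list[dict] = []
    gene_enhancer_idx: dict[str, list[int]] = {g: [] for g in gene_ids}
    seen_intervals: set[tuple[int, int]] = set()
    width = config.peak_width
    lo_d, hi_d = config.enhancer_distance_range

    def _add_peak(start: int, end: int, rate: np.ndarray, exact: bool = False) -> int:
        if exact and (start, end) in seen_intervals:
            raise ValueError(f"duplicate peak interval [{start}, {end})")
        while (start, end) in seen_intervals:  # deterministic de-collision
            start, end = start + 1, end + 1
        seen_intervals.add((start, end))
        peaks.append(io.Peak(chrom, start, end, rng.uniform(0.3, 0.7)))
        peak_rate_rows.append(rate)
        return len(peaks) - 1

    for gi, gene in enumerate(genes):
        gene_rate = rates[gi]
        # promoter: covers the TSS, flat accessibility
        p_start = gene.tss - width // 2
        flat = np.full(n_cells, rng.uniform(0.5, 1.5))
        pidx = _add_peak(p_start, p_start + width, _noisy(flat))
        link_rows.append(
            {
                "peak_index": pidx,
                "gene_id": gene.gene_id,
                "tss_distance": 0,
                "kind": "promoter",
                "is_dynamic": bool(dynamic_gene[gi]),
            }
        )
        for _ in range(config.enhancers_per_gene):
            # resample on the (vanishingly rare) interval collision so the
            # planted distance is never perturbed across the 2 kb boundary
            while True:
                d = int(rng.integers(lo_d, hi_d + 1))
                if rng.random() < 0.5:
                    start = gene.tss + d
                else:
                    start = gene.tss - d + 1 - width
                if (start, start + width) not in seen_intervals:
                    break
            eidx = _add_peak(start, start + width, _noisy(gene_rate), exact=True)
            link_rows.append(
                {
                    "peak_index": eidx,
                    "gene_id": gene.gene_id,
                    "tss_distance": io.tss_distance(
                        peaks[eidx].start, peaks[eidx].end, gene.tss
                    ),
                    "kind": "enhancer",
                    "is_dynamic": bool(dynamic_gene[gi]),
                }
            )
            gene_enhancer_idx[gene.gene_id].append(eidx)

    genome_end = 200_000 + n_genes * config.tss_spacing
    for _ in range(config.n_decoy_peaks):
        start = int(rng.integers(0, genome_end))
        flat = np.full(n_cells, rng.uniform(0.5, 1.5))
        _add_peak(start, start + width, _noisy(flat))

    planted_links = pd.DataFrame(
        link_rows, columns=["peak_index", "gene_id", "tss_distance", "kind", "is_dynamic"]
    )

    # (5) motif matrix: planted matches in target enhancers + false positives
    all_tf_ids = tf_ids + decoy_tf_ids
    n_peaks = len(peaks)
    motif = np.zeros((n_peaks, len(all_tf_ids)), dtype=np.int8)
    for _, e in planted_edges.iterrows():
        k = tf_ids.index(e["tf"])
        for pidx in gene_enhancer_idx[e["gene"]]:
            motif[pidx, k] = 1
    if config.motif_false_match_rate > 0:
        motif |= (rng.random(motif.shape) < config.motif_false_match_rate).astype(np.int8)
    tf_to_gene = dict(zip(all_tf_ids, tf_gene_ids + decoy_tf_gene_ids))
    motifs = io.MotifMatches(sp.csc_matrix(motif), all_tf_ids, tf_to_gene)

    # (6) counts; ATAC rates get the same mass balancing over dynamic peaks
    peak_rates = np.asarray(peak_rate_rows)
    dynamic_peak = np.zeros(len(peaks), bool)
    for link in link_rows:
        if link["kind"] == "enhancer" and link["is_dynamic"]:
            dynamic_peak[link["peak_index"]] = True
    peak_rates = _mass_balance(peak_rates, dynamic_peak)
    rna_counts = _sample_counts(rates, config.depth_rna, rng, config.nb_dispersion)
    atac_counts = _sample_counts(peak_rates, config.depth_atac, rng, config.nb_dispersion)
    rna = io.CountMatrix(rna_counts, gene_ids, cell_ids)
    atac = io.CountMatrix(atac_counts, [p.name for p in peaks], cell_ids)

    cells = pd.DataFrame(
        {"cell_id": cell_ids, "modality": "PAIRED", "cluster": clusters.values}
    )
    truth = GroundTruth(
        planted_edges=planted_edges,
        planted_links=planted_links,
        true_pseudotime=pd.Series(t, index=cell_ids),
        cluster_labels=clusters,
    )
    return SimulatedMultiome(rna, atac, peaks, genes, motifs, cells, truth, config)
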