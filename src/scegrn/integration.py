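"""Cross-modality integration: shared co-embedding and one-to-one cell pairing.

Unpaired RNA and ATAC cells are placed in a common space by canonical
correlation analysis over a shared gene feature set: RNA uses log-normalized
expression, ATAC uses gene activity scores (peak counts summed over the gene
body plus an upstream window). The CCA is realized as the SVD of the
standardized cross-feature product K = X_rna^T X_atac, computed through thin
QR factorizations so it is deterministic; sign indeterminacy is fixed so each
component's largest-magnitude cell coordinate is positive, and cell rows are
L2-normalized, making Euclidean distance monotone in cosine distance.

Cells are then paired one-to-one by minimum-total-cost assignment on
cross-modality distances, restricted to each cell's k nearest cross-modality
neighbors (non-candidates get a prohibitive cost). Problems up to a few
thousand cells per side are solved exactly with the dense Hungarian-type
solver; larger problems use the sparse exact solver on candidate costs, with
a dense fallback when the restriction is infeasible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import min_weight_full_bipartite_matching
from scipy.spatial.distance import cdist

from scegrn._stats import lognorm_cp10k
from scegrn.io import CountMatrix, GeneAnnotation, Peak

logger = logging.getLogger(__name__)

# Per-side size up to which the dense exact solver is used. The dense
# Hungarian-type solver with prohibitive non-candidate costs is fast and
# memory-bounded up to several thousand cells per side; beyond that the
# sparse exact solver on the k-candidate graph takes over.
_DENSE_LIMIT = 6000


@dataclass
class Embedding:
    """Cell coordinates in a shared co-embedding space."""

    coords: np.ndarray
    cell_ids: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 2 or self.coords.shape[0] != len(self.cell_ids):
            raise ValueError("coords must be (n_cells, n_dims) aligned with cell_ids")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding contains non-finite entries")


@dataclass
class Pairing:
    """One-to-one RNA-ATAC cell matching with per-pair costs."""

    pairs: list[tuple[str, str]]
    costs: np.ndarray
    total_cost: float
    unmatched_rna: list[str] = field(default_factory=list)
    unmatched_atac: list[str] = field(default_factory=list)
    restricted: bool = True

    def __post_init__(self) -> None:
        rna_side = [r for r, _ in self.pairs]
        atac_side = [a for _, a in self.pairs]
        if len(set(rna_side)) != len(rna_side) or len(set(atac_side)) != len(atac_side):
            raise ValueError("pairing is not one-to-one")


# ---------------------------------------------------------------------------
# gene activity
# ---------------------------------------------------------------------------


def gene_activity_scores(
    atac: CountMatrix,
    peaks: list[Peak],
    genes: list[GeneAnnotation],
    upstream_bp: int = 100_000,
) -> CountMatrix:
    """Sum ATAC counts of peaks overlapping each gene's activity window.

    The window is the gene body (or the TSS base alone when no body is
    annotated) extended ``upstream_bp`` upstream of the TSS, strand-aware.
    The generous default upstream extension captures distal regulatory peaks
    whose accessibility tracks expression, in the spirit of gene score models
    that weight peaks within ~100 kb of the TSS. A peak overlapping two
    genes' windows is counted for both; genes with no overlapping peak keep
    an all-zero row.
    """
    if len(peaks) != atac.shape[0]:
        raise ValueError("peaks must align with ATAC matrix rows")
    peak_chroms = np.array([p.chrom for p in peaks])
    peak_starts = np.array([p.start for p in peaks])
    peak_ends = np.array([p.end for p in peaks])
    chrom_set = set(peak_chroms)

    rows, cols = [], []
    for gi, gene in enumerate(genes):
        if gene.chrom not in chrom_set:
            logger.warning("gene %s: chromosome %s has no peaks", gene.gene_id, gene.chrom)
            continue
        body_start = gene.start if gene.start is not None else gene.tss
        body_end = gene.end if gene.end is not None else gene.tss + 1
        if gene.strand == "+":
            win_start, win_end = max(0, body_start - upstream_bp), body_end
        else:
            win_start, win_end = body_start, body_end + upstream_bp
        mask = (peak_chroms == gene.chrom) & (peak_starts < win_end) & (peak_ends > win_start)
        hit = np.flatnonzero(mask)
        rows.extend([gi] * hit.size)
        cols.extend(hit.tolist())

    weights = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(genes), len(peaks))
    )
    activity = weights @ atac.values
    return CountMatrix(activity, [g.gene_id for g in genes], list(atac.cell_ids))


# ---------------------------------------------------------------------------
# joint embedding (CCA)
# ---------------------------------------------------------------------------


def _standardize_features(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def joint_embedding(
    rna: CountMatrix,
    activity: CountMatrix,
    n_dims: int = 30,
    n_features: int = 2000,
) -> tuple[Embedding, Embedding]:
    """Co-embed RNA cells and ATAC cells (via gene activity) with CCA.

    Features are the ``n_features`` most variable shared genes, measured on
    log-normalized RNA (ties broken by gene id). Both matrices are
    log-normalized (counts per 10k, log1p) and feature-standardized before
    the cross-product SVD. Deterministic up to nothing: signs are fixed so
    each component's largest-magnitude cell coordinate is positive.
    """
    shared = sorted(set(rna.feature_ids) & set(activity.feature_ids))
    if len(shared) < n_dims:
        raise ValueError(
            f"only {len(shared)} shared features but n_dims={n_dims} requested"
        )
    rna_shared = rna.subset_features(shared)
    act_shared = activity.subset_features(shared)

    rna_log = lognorm_cp10k(rna_shared.values)
    variances = rna_log.var(axis=1)
    order = sorted(range(len(shared)), key=lambda i: (-variances[i], shared[i]))
    sel = sorted(order[: min(n_features, len(shared))])
    features = [shared[i] for i in sel]
    if len(features) < n_dims:
        raise ValueError("fewer selected features than requested dimensions")

    a = _standardize_features(rna_log[sel])  # features x n_rna
    b = _standardize_features(lognorm_cp10k(act_shared.values)[sel])  # features x n_atac

    # K = a.T b via thin QR of each side: deterministic, never forms cells x cells
    q_a, r_a = np.linalg.qr(a.T)
    q_b, r_b = np.linalg.qr(b.T)
    u, s, vt = np.linalg.svd(r_a @ r_b.T)
    k = min(n_dims, s.size)
    coords_rna = q_a @ u[:, :k] * s[:k]
    coords_atac = q_b @ vt[:k].T * s[:k]

    for j in range(k):
        stacked = np.concatenate([coords_rna[:, j], coords_atac[:, j]])
        pivot = np.argmax(np.abs(stacked))
        if stacked[pivot] < 0:
            coords_rna[:, j] *= -1
            coords_atac[:, j] *= -1

    def _l2(c: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(c, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return c / norms

    return (
        Embedding(_l2(coords_rna), list(rna.cell_ids), "RNA"),
        Embedding(_l2(coords_atac), list(activity.cell_ids), "ATAC"),
    )


def pca_embedding(rna: CountMatrix, n_dims: int = 30) -> Embedding:
    """Deterministic PCA of log-normalized expression, for paired protocols
    where no cross-modality co-embedding is needed (e.g. 10x Multiome)."""
    x = lognorm_cp10k(rna.values)
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    k = min(n_dims, s.size)
    coords = u[:, :k] * s[:k]
    for j in range(k):
        pivot = np.argmax(np.abs(coords[:, j]))
        if coords[pivot, j] < 0:
            coords[:, j] *= -1
    return Embedding(coords, list(rna.cell_ids), "PAIRED")


# ---------------------------------------------------------------------------
# cell pairing
# ---------------------------------------------------------------------------


def _candidate_mask(dist: np.ndarray, k: int) -> np.ndarray:
    """Union of row-wise and column-wise k-nearest-neighbor candidacy."""
    n_r, n_a = dist.shape
    mask = np.zeros_like(dist, dtype=bool)
    kk_r = min(k, n_a)
    kk_a = min(k, n_r)
    row_nn = np.argpartition(dist, kk_r - 1, axis=1)[:, :kk_r]
    mask[np.arange(n_r)[:, None], row_nn] = True
    col_nn = np.argpartition(dist, kk_a - 1, axis=0)[:kk_a, :]
    mask[col_nn, np.arange(n_a)[None, :]] = True
    return mask


def pair_cells(
    emb_rna: Embedding,
    emb_atac: Embedding,
    k_candidates: int = 10,
) -> Pairing:
    """Minimum-total-cost one-to-one matching of RNA to ATAC cells.

    Cost is Euclidean distance in the co-embedding, restricted to each cell's
    ``k_candidates`` nearest cross-modality neighbors. The assignment is
    solved exactly; min(n_RNA, n_ATAC) pairs are returned and the surplus
    side's unmatched cells are listed.
    """
    if k_candidates < 1:
        raise ValueError("k_candidates must be >= 1")
    if emb_rna.coords.shape[1] != emb_atac.coords.shape[1]:
        raise ValueError("embeddings live in different spaces")
    dist = cdist(emb_rna.coords, emb_atac.coords)
    n_r, n_a = dist.shape
    mask = _candidate_mask(dist, k_candidates)
    restricted = True

    if max(n_r, n_a) <= _DENSE_LIMIT:
        prohibitive = dist.max() * max(n_r, n_a) + 1.0
        cost = np.where(mask, dist, prohibitive)
        rows, cols = linear_sum_assignment(cost)
        if not mask[rows, cols].all():
            warnings.warn(
                "candidate restriction infeasible; matching fell back to "
                "unrestricted costs for some cells",
                stacklevel=2,
            )
            rows, cols = linear_sum_assignment(dist)
            restricted = False
    else:
        shift = 1e-9  # sparse solver drops explicit zeros; constant shift is rank-safe
        graph = sp.csr_matrix(np.where(mask, dist + shift, 0.0))
        try:
            rows, cols = min_weight_full_bipartite_matching(graph)
        except ValueError:
            warnings.warn(
                "candidate restriction infeasible; matching fell back to "
                "the unrestricted dense solver",
                stacklevel=2,
            )
            rows, cols = linear_sum_assignment(dist)
            restricted = False

    costs = dist[rows, cols]
    pairs = [(emb_rna.cell_ids[r], emb_atac.cell_ids[c]) for r, c in zip(rows, cols)]
    matched_r, matched_a = set(rows.tolist()), set(cols.tolist())
    return Pairing(
        pairs=pairs,
        costs=costs,
        total_cost=float(costs.sum()),
        unmatched_rna=[emb_rna.cell_ids[i] for i in range(n_r) if i not in matched_r],
        unmatched_atac=[emb_atac.cell_ids[i] for i in range(n_a) if i not in matched_a],
        restricted=restricted,
    )


def evaluate_pairing(
    pairing: Pairing,
    truth_pairs: list[tuple[str, str]],
    cluster_labels: dict[str, str],
) -> dict[str, float]:
    """Score a pairing against ground truth.

    Returns the number of exactly recovered pairs and the fraction of pairs
    whose two cells carry the same cluster label (cell-type accuracy).
    """
    truth = set(truth_pairs)
    exact = sum(1 for p in pairing.pairs if p in truth)
    same = [
        cluster_labels.get(r) is not None
        and cluster_labels.get(r) == cluster_labels.get(a)
        for r, a in pairing.pairs
    ]
    accuracy = float(np.mean(same)) if same else 0.0
    return {"exact_pair_recovery": float(exact), "celltype_accuracy": accuracy}
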