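"""Per-cell TF activity as bias-corrected motif-deviation z-scores.

For each TF, the observed accessibility in its motif-matched peaks is
compared with the expectation under a uniform read-fraction model, and the
resulting raw deviation is standardized against deviations of background
peak sets matched on GC content and mean accessibility. Concretely, with
``X`` the peak x cell count matrix, per-cell totals ``t_c``, and read
fractions ``a_p = sum_c X[p,c] / sum_{p,c} X[p,c]``:

    observed   O[k,c] = sum_p M[p,k] * X[p,c]
    expected   E[k,c] = t_c * sum_p M[p,k] * a_p
    raw dev    Y[k,c] = (O[k,c] - E[k,c]) / E[k,c]

Background deviations ``Y_b`` repeat the computation with every motif peak
replaced by its sampled background partner in iteration ``b``; the z-score is
``(Y - mean_b Y_b) / sd_b Y_b`` with the sample standard deviation
(n-1 denominator). A motif matching all peaks has zero deviation everywhere,
and scaling all counts by a constant leaves raw deviations unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from scegrn.io import CountMatrix, MotifMatches, Peak

logger = logging.getLogger(__name__)


@dataclass
class BackgroundPeaks:
    """Sampled background peak indices: one column per iteration."""

    indices: np.ndarray  # (n_peaks, n_iterations) int
    n_iterations: int
    seed: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, int)
        if self.indices.ndim != 2 or self.indices.shape[1] != self.n_iterations:
            raise ValueError("indices must be (n_peaks, n_iterations)")
        if self.indices.min() < 0 or self.indices.max() >= self.indices.shape[0]:
            raise ValueError("background index out of range")


@dataclass
class ActivityMatrix:
    """TF x cell motif-deviation z-scores (and raw deviations).

    TFs with no matched peak or no expected reads are dropped; ``dropped``
    maps each such TF to the reason. Entries whose background sd is zero are
    NaN and flagged in ``unstable_entries``.
    """

    z: np.ndarray
    raw_dev: np.ndarray
    tf_ids: list[str]
    dropped: dict[str, str] = field(default_factory=dict)
    unstable_entries: int = 0

    def __post_init__(self) -> None:
        if self.z.shape != self.raw_dev.shape or self.z.shape[0] != len(self.tf_ids):
            raise ValueError("inconsistent ActivityMatrix dimensions")

    def row(self, tf_id: str) -> np.ndarray:
        return self.z[self.tf_ids.index(tf_id)]


def background_peaks(
    peaks: list[Peak],
    mean_accessibility: np.ndarray,
    n_neighbors: int = 50,
    n_iterations: int = 50,
    seed: int = 1,
) -> BackgroundPeaks:
    """Sample GC/accessibility-matched background peaks for bias correction.

    Peaks are placed in a 2-D covariate space of (gc_fraction,
    log1p(mean accessibility)), standardized to zero mean and unit variance.
    Each peak's candidate pool is its ``n_neighbors`` nearest peaks (Euclidean,
    excluding itself); each of the ``n_iterations`` columns samples one pool
    member uniformly with replacement. Fixed ``seed`` makes sampling
    bit-reproducible.
    """
    n_peaks = len(peaks)
    if n_neighbors >= n_peaks:
        raise ValueError(f"n_neighbors ({n_neighbors}) must be < n_peaks ({n_peaks})")
    gc = np.array([p.gc_fraction for p in peaks], float)
    if np.isnan(gc).any():
        raise ValueError("all peaks need gc_fraction for background matching")
    acc = np.log1p(np.asarray(mean_accessibility, float))
    if acc.size != n_peaks:
        raise ValueError("mean_accessibility length must match peaks")

    feats = np.column_stack([gc, acc])
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / sd

    # brute-force kNN with a stable sort keeps ties deterministic; peak sets
    # at this scale (<= tens of thousands) fit comfortably in memory chunks
    pools = np.empty((n_peaks, n_neighbors), dtype=int)
    chunk = max(1, int(2e7) // max(n_peaks, 1))
    for lo in range(0, n_peaks, chunk):
        hi = min(lo + chunk, n_peaks)
        d2 = ((feats[lo:hi, None, :] - feats[None, :, :]) ** 2).sum(axis=2)
        d2[np.arange(hi - lo), np.arange(lo, hi)] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")
        pools[lo:hi] = order[:, :n_neighbors]

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_neighbors, size=(n_peaks, n_iterations))
    indices = pools[np.arange(n_peaks)[:, None], draws]
    return BackgroundPeaks(indices, n_iterations, seed)


def _deviations(
    motif_csc: sp.csc_matrix, x: sp.csr_matrix, a: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """(O - E) / E per TF x cell; entries with E == 0 are returned as 0."""
    observed = np.asarray((motif_csc.T @ x).todense())
    expected = np.outer(np.asarray(motif_csc.T @ a).ravel(), t)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = (observed - expected) / expected
    dev[expected == 0] = 0.0
    return dev


def deviation_zscores(
    atac: CountMatrix,
    motifs: MotifMatches,
    background: BackgroundPeaks,
) -> ActivityMatrix:
    """Compute bias-corrected motif-deviation z-scores per TF and cell."""
    x = sp.csr_matrix(atac.values, dtype=float)
    n_peaks, n_cells = x.shape
    if motifs.n_peaks != n_peaks:
        raise ValueError("motif matrix rows must match ATAC peaks")
    if background.indices.shape[0] != n_peaks:
        raise ValueError("background indices must match ATAC peaks")

    t = np.asarray(x.sum(axis=0)).ravel()
    total = t.sum()
    if total == 0:
        raise ValueError("ATAC matrix has no reads")
    a = np.asarray(x.sum(axis=1)).ravel() / total

    m = sp.csc_matrix(motifs.indicator, dtype=float)
    matched = np.asarray(m.sum(axis=0)).ravel()
    expected_frac = np.asarray(m.T @ a).ravel()

    dropped: dict[str, str] = {}
    keep: list[int] = []
    for k, tf in enumerate(motifs.tf_ids):
        if matched[k] == 0:
            dropped[tf] = "no matched peaks"
        elif expected_frac[k] == 0:
            dropped[tf] = "no reads in matched peaks"
        else:
            keep.append(k)
    if dropped:
        logger.info("dropping %d TFs from activity scoring: %s", len(dropped), dropped)
    m_kept = sp.csc_matrix(m[:, keep])
    tf_ids = [motifs.tf_ids[k] for k in keep]

    raw = _deviations(m_kept, x, a, t)

    n_iter = background.n_iterations
    bg_sum = np.zeros_like(raw)
    bg_sumsq = np.zeros_like(raw)
    for b in range(n_iter):
        idx = background.indices[:, b]
        dev_b = _deviations(m_kept, x[idx, :], a[idx], t)
        bg_sum += dev_b
        bg_sumsq += dev_b**2
    bg_mean = bg_sum / n_iter
    # sample variance with n-1 denominator; clip tiny negatives from roundoff
    bg_var = np.maximum(bg_sumsq - n_iter * bg_mean**2, 0.0) / (n_iter - 1)
    bg_sd = np.sqrt(bg_var)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (raw - bg_mean) / bg_sd
    unstable = int((bg_sd == 0).sum())
    z[bg_sd == 0] = np.nan
    return ActivityMatrix(z, raw, tf_ids, dropped, unstable)
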