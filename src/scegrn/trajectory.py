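"""Supervised pseudotime over an ordered cluster path, and binning along it.

The trajectory is supervised: the user names an ordered sequence of cluster
labels (root first, terminal last) and every member cell receives a scalar
pseudotime on [0, 100]. Within each cluster, cells are ordered by their
scalar projection onto the direction from that cluster's centroid to the next
one (the last cluster projects along the incoming direction); raw times are
then rank-transformed over all member cells and rescaled, which makes the
result robust to uneven centroid spacing.

Any feature x cell matrix can be summarized along the trajectory with
:func:`bin_smooth`: equal-width pseudotime bins, per-bin means, empty bins
filled from their nearest occupied neighbor, then a truncated moving average.
All trajectory-conditioned correlations downstream are computed on these
binned profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata


@dataclass
class Trajectory:
    """Per-cell pseudotime on [0, 100] over an ordered cluster path."""

    cell_ids: list[str]
    pseudotime: np.ndarray
    ordered_groups: list[str]

    def __post_init__(self) -> None:
        self.pseudotime = np.asarray(self.pseudotime, float)
        if len(self.cell_ids) != self.pseudotime.size:
            raise ValueError("cell_ids and pseudotime lengths differ")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "pseudotime": self.pseudotime})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, ordered_groups: list[str]) -> "Trajectory":
        return cls(frame["cell_id"].tolist(), frame["pseudotime"].to_numpy(), ordered_groups)


@dataclass
class BinnedMatrix:
    """Feature x bin matrix of smoothed per-bin means along a trajectory."""

    values: np.ndarray
    bin_centers: np.ndarray
    feature_ids: list[str]
    window: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.bin_centers = np.asarray(self.bin_centers, float)
        if self.values.shape[0] != len(self.feature_ids):
            raise ValueError("values rows and feature_ids lengths differ")
        if self.values.shape[1] != self.bin_centers.size:
            raise ValueError("values columns and bin_centers lengths differ")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")

    def subset(self, ids: list[str]) -> "BinnedMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[i] for i in ids]
        return BinnedMatrix(self.values[rows], self.bin_centers, list(ids), self.window)

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """First right singular vector of the centered coordinates, sign-fixed so
    its largest-magnitude component is positive."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    pivot = np.argmax(np.abs(axis))
    return axis if axis[pivot] >= 0 else -axis


def supervised_pseudotime(
    coords: np.ndarray,
    cell_ids: list[str],
    cluster_labels: list[str] | np.ndarray,
    ordered_groups: list[str],
    terminal_cells: list[str] | None = None,
) -> Trajectory:
    """Assign pseudotime on [0, 100] along a user-ordered cluster path.

    Parameters
    ----------
    coords
        cells x dims embedding (rows aligned with ``cell_ids``).
    cluster_labels
        Per-cell cluster label; cells whose label is not in ``ordered_groups``
        are excluded from the trajectory.
    ordered_groups
        Cluster labels from root to terminal. With a single group the path
        direction falls back to the group's principal axis, oriented toward
        ``terminal_cells`` when given.
    """
    coords = np.asarray(coords, float)
    labels = np.asarray(cluster_labels)
    if coords.shape[0] != len(cell_ids) or labels.size != len(cell_ids):
        raise ValueError("coords, cell_ids and cluster_labels must align")
    if len(ordered_groups) == 0:
        raise ValueError("ordered_groups is empty")
    if len(set(ordered_groups)) != len(ordered_groups):
        raise ValueError("ordered_groups contains duplicates")
    group_masks = []
    for g in ordered_groups:
        mask = labels == g
        if not mask.any():
            raise ValueError(f"group {g!r} absent from cluster labels")
        if mask.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 member cells")
        group_masks.append(mask)

    centroids = np.stack([coords[m].mean(axis=0) for m in group_masks])
    m = len(ordered_groups)
    directions = []
    if m == 1:
        axis = _principal_axis(coords[group_masks[0]])
        if terminal_cells:
            term = np.isin(np.asarray(cell_ids), terminal_cells)
            if term.any():
                proj = (coords[term] - centroids[0]) @ axis
                if proj.mean() < 0:
                    axis = -axis
        directions.append(axis)
    else:
        for i in range(m):
            if i < m - 1:
                vec = centroids[i + 1] - centroids[i]
            else:
                vec = centroids[i] - centroids[i - 1]
            norm = np.linalg.norm(vec)
            directions.append(vec / norm if norm > 0 else np.zeros_like(vec))

    member = np.zeros(len(cell_ids), bool)
    raw = np.full(len(cell_ids), np.nan)
    for i, mask in enumerate(group_masks):
        member |= mask
        direction = directions[0] if m == 1 else directions[i]
        proj = (coords[mask] - centroids[i]) @ direction
        span = proj.max() - proj.min()
        s = (proj - proj.min()) / span if span > 0 else np.full(proj.shape, 0.5)
        raw[mask] = i + s

    raw_member = raw[member]
    ranks = rankdata(raw_member, method="average")
    if ranks.max() > ranks.min():
        pt = (ranks - ranks.min()) / (ranks.max() - ranks.min()) * 100.0
    else:
        pt = np.zeros_like(ranks)
    member_ids = [c for c, keep in zip(cell_ids, member) if keep]
    return Trajectory(member_ids, pt, list(ordered_groups))


def bin_smooth(
    matrix: np.ndarray | sp.spmatrix,
    feature_ids: list[str],
    trajectory: Trajectory,
    n_bins: int = 100,
    window: int = 5,
) -> BinnedMatrix:
    """Bin a feature x member-cell matrix along pseudotime and smooth it.

    Cells fall into ``n_bins`` equal-width bins spanning the observed
    pseudotime range; each bin takes the mean over its member cells; empty
    bins inherit the value of the nearest occupied bin (ties to the left);
    a moving average of ``window`` bins (truncated at the edges) smooths the
    result. Columns must align with ``trajectory.cell_ids``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if window < 1:
        raise ValueError("window must be >= 1")
    dense = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, float)
    if dense.shape[1] != len(trajectory.cell_ids):
        raise ValueError("matrix columns must align with trajectory cells")

    pt = trajectory.pseudotime
    lo, hi = pt.min(), pt.max()
    width = (hi - lo) / n_bins if hi > lo else 1.0
    idx = np.minimum(((pt - lo) / width).astype(int), n_bins - 1)
    edges = lo + width * np.arange(n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0

    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.zeros((dense.shape[0], n_bins))
    np.add.at(sums.T, idx, dense.T)
    occupied = counts > 0
    means = np.zeros_like(sums)
    means[:, occupied] = sums[:, occupied] / counts[occupied]

    if not occupied.all():
        occ_idx = np.flatnonzero(occupied)
        for b in np.flatnonzero(~occupied):
            nearest = occ_idx[np.argmin(np.abs(occ_idx - b))]
            means[:, b] = means[:, nearest]

    if window > 1:
        left = (window - 1) // 2
        right = window // 2
        csum = np.cumsum(np.concatenate([np.zeros((dense.shape[0], 1)), means], axis=1), axis=1)
        smoothed = np.empty_like(means)
        for b in range(n_bins):
            a, z = max(0, b - left), min(n_bins, b + right + 1)
            smoothed[:, b] = (csum[:, z] - csum[:, a]) / (z - a)
        means = smoothed

    return BinnedMatrix(means, centers, list(feature_ids), window)
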