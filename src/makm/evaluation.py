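"""Segmentation-quality metrics: Dice overlap and percentile Hausdorff.

Interfaces between adjacent layers are represented as point clouds — the
physical midpoints of voxel faces separating the two labels — and compared
with percentile Hausdorff distances.  The classical (100th percentile)
Hausdorff distance is notoriously outlier-sensitive, particularly at
surface edges, so the 50th/75th/95th percentiles of the pooled
bidirectional nearest-neighbor distances are reported alongside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .labeling import LabelImage

__all__ = [
    "BoundaryPointSet",
    "dice",
    "extract_interface",
    "percentile_hausdorff",
]


@dataclass
class BoundaryPointSet:
    """Physical coordinates (mm) of points on a label-label interface."""

    points: np.ndarray  # (n_points, ndim)
    interface: str = ""

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    def __len__(self) -> int:
        return 0 if self.points.size == 0 else self.points.shape[0]


def dice(a: LabelImage, b: LabelImage, label: int) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of one label's voxel sets (1 if both empty)."""
    if a.labels.shape != b.labels.shape:
        raise ValueError("label images live on different grids")
    A = a.labels == label
    B = b.labels == label
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((A & B).sum()) / (na + nb)


def extract_interface(labels: LabelImage, k: int, k_next: int) -> BoundaryPointSet:
    """Midpoints of voxel faces separating label ``k`` from label ``k_next``.

    Coordinates are physical (index times spacing), one point per adjacent
    opposite-label voxel-face pair, collected along every grid axis.  An
    empty set (labels present but nowhere adjacent) is returned with a
    warning.
    """
    arr = labels.labels
    if not (arr == k).any() or not (arr == k_next).any():
        raise ValueError(f"label {k} or {k_next} absent from the image")
    spacing = np.asarray(labels.spacing)
    pts = []
    for ax in range(arr.ndim):
        lo = [slice(None)] * arr.ndim
        hi = [slice(None)] * arr.ndim
        lo[ax] = slice(None, -1)
        hi[ax] = slice(1, None)
        a, b = arr[tuple(lo)], arr[tuple(hi)]
        hit = ((a == k) & (b == k_next)) | ((a == k_next) & (b == k))
        idx = np.argwhere(hit).astype(float)
        idx[:, ax] += 0.5  # face midpoint between voxel centers
        pts.append(idx * spacing)
    pts = np.concatenate(pts, axis=0)
    if pts.shape[0] == 0:
        warnings.warn(f"labels {k} and {k_next} are nowhere adjacent")
    return BoundaryPointSet(
        points=pts.reshape(-1, arr.ndim), interface=f"{k}/{k_next}"
    )


def percentile_hausdorff(
    a: BoundaryPointSet, b: BoundaryPointSet, p: float = 100.0
) -> float:
    """p-th percentile of pooled bidirectional nearest-neighbor distances (mm).

    Directed nearest-neighbor distances from every point of ``a`` to ``b``
    are pooled with those from ``b`` to ``a``; the percentile uses linear
    interpolation.  ``p=100`` is the classical symmetric Hausdorff maximum.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("boundary point sets must be nonempty")
    d_ab = cKDTree(b.points).query(a.points)[0]
    d_ba = cKDTree(a.points).query(b.points)[0]
    pooled = np.concatenate([d_ab, d_ba])
    return float(np.percentile(pooled, p))
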