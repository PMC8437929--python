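"""Shared voxel-grid geometry helpers.

Conventions used throughout the package:

* streamline / point coordinates are world millimetres in the frame of the
  volume's NIfTI affine (RAS expected but not enforced);
* voxel indices are 0-based; a voxel is the half-open cube centred on the
  world position of its index point, extending half a voxel size each way.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "voxel_sizes",
    "is_axis_aligned",
    "world_to_voxel",
    "voxel_to_world",
    "nearest_voxel",
    "in_bounds",
    "resample_polyline",
    "polyline_length",
]


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Edge lengths (mm) of a voxel, one per axis."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def is_axis_aligned(affine: np.ndarray, tol: float = 1e-6) -> bool:
    """True when each voxel axis maps onto a single world axis (diagonal 3x3)."""
    rot = np.abs(np.asarray(affine, dtype=float)[:3, :3])
    off = rot - np.diag(np.diag(rot))
    return bool(np.all(off <= tol * max(1.0, rot.max())))


def world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map world-mm points (..., 3) to continuous voxel coordinates."""
    inv = np.linalg.inv(affine)
    pts = np.asarray(points, dtype=float)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def voxel_to_world(affine: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Map (continuous or integer) voxel coordinates (..., 3) to world mm."""
    aff = np.asarray(affine, dtype=float)
    idx = np.asarray(indices, dtype=float)
    return idx @ aff[:3, :3].T + aff[:3, 3]


def nearest_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Integer voxel index containing each world point (round-to-nearest)."""
    return np.round(world_to_voxel(affine, points)).astype(np.int64)


def in_bounds(indices: np.ndarray, shape) -> np.ndarray:
    """Boolean mask of index rows that fall inside a 3D array of `shape`."""
    idx = np.asarray(indices)
    ok = np.ones(idx.shape[:-1], dtype=bool)
    for ax in range(3):
        ok &= (idx[..., ax] >= 0) & (idx[..., ax] < shape[ax])
    return ok


def polyline_length(points: np.ndarray) -> float:
    """Arc length (mm) of an ordered point sequence."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample an ordered polyline at (approximately) uniform arc length.

    The first and last original points are always retained, so no segment is
    ever skipped: every stretch of the path is sampled at spacing <= ``step``.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return pts.copy()
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total == 0.0:
        return pts[:1].copy()
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(total / step)), 1)
    s = np.linspace(0.0, total, n + 1)
    out = np.empty((n + 1, 3))
    for ax in range(3):
        out[:, ax] = np.interp(s, cum, pts[:, ax])
    return out
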