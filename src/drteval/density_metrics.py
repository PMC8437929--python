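"""Streamline-density rendering, template warping, and congruence metrics.

Two tract renditions are compared in template space by (1) the Euclidean
distance of the slice-wise 2D centre of gravity (COG) of their streamline
densities, taken at every integer template-z millimetre inside an evaluation
range, and (2) the Dice coefficient of the densities binarised at a
streamline-count threshold.  Anatomical validity places the per-level COG
against reference nucleus masks (Vim, RN/STN, SCP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from ._grid import (in_bounds, is_axis_aligned, nearest_voxel,
                    resample_polyline, voxel_sizes, voxel_to_world)
from .io_formats import Tractogram

__all__ = [
    "DensityMap",
    "MetricParams",
    "CongruenceResult",
    "ValidityResult",
    "render_density",
    "warp_density",
    "slice_cog",
    "cog_distance_profile",
    "dice_profile",
    "congruence_profile",
    "validity_cog",
]

#: default transversal evaluation levels (template z, mm): ventral
#: intermediate nucleus, red nucleus + subthalamic nucleus, superior
#: cerebellar peduncle.
DEFAULT_EVAL_LEVELS = {"vim": 6.0, "rn_stn": -8.0, "scp": -22.0}


@dataclass
class DensityMap:
    """Per-voxel streamline visitation counts.

    Native-space maps hold integer counts (each streamline counted at most
    once per voxel); template-space maps hold interpolated real values.
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "native"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("density map must be 3D")
        if np.any(self.data < 0):
            raise ValueError("density values must be >= 0")
        if self.space_tag not in ("native", "template"):
            raise ValueError("space_tag must be native|template")


@dataclass
class MetricParams:
    """Evaluation range and thresholds for the congruence statistics.

    The z range [-27, 16] mm (inclusive, template coordinates) covers the
    tract segment relevant for stereotactic targeting; the Dice threshold
    is 2 streamlines per voxel.
    """

    z_min: float = -27.0
    z_max: float = 16.0
    dice_threshold: float = 2.0
    eval_levels: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVAL_LEVELS))

    def __post_init__(self) -> None:
        if self.z_min >= self.z_max:
            raise ValueError("need z_min < z_max")
        if self.dice_threshold <= 0:
            raise ValueError("dice_threshold must be > 0")
        for name, z in self.eval_levels.items():
            if not (self.z_min <= z <= self.z_max):
                raise ValueError(f"eval level {name}={z} outside [z_min, z_max]")

    def z_levels(self) -> np.ndarray:
        """One evaluation per integer mm from z_min to z_max inclusive."""
        return np.arange(np.ceil(self.z_min), np.floor(self.z_max) + 1)


@dataclass
class CongruenceResult:
    """Per-z COG distances and Dice values plus aggregates.

    ``z`` are template-mm levels; undefined levels (zero mass / empty
    suprathreshold sets on a slice) carry NaN and are excluded from the
    aggregates, whose basis is reported in ``n_defined_*``.
    """

    z: np.ndarray
    cog_distance_mm: np.ndarray
    dice: np.ndarray
    label: str = ""

    @property
    def n_defined_cog(self) -> int:
        return int(np.isfinite(self.cog_distance_mm).sum())

    @property
    def n_defined_dice(self) -> int:
        return int(np.isfinite(self.dice).sum())

    def aggregate(self) -> Dict[str, float]:
        d = self.cog_distance_mm[np.isfinite(self.cog_distance_mm)]
        k = self.dice[np.isfinite(self.dice)]
        return {
            "cog_mean_mm": float(np.mean(d)) if d.size else float("nan"),
            "cog_median_mm": float(np.median(d)) if d.size else float("nan"),
            "dice_mean": float(np.mean(k)) if k.size else float("nan"),
            "dice_median": float(np.median(k)) if k.size else float("nan"),
            "n_defined_cog": self.n_defined_cog,
            "n_defined_dice": self.n_defined_dice,
        }

    def at_level(self, z_level: float) -> Dict[str, float]:
        i = int(np.argmin(np.abs(self.z - z_level)))
        return {"z": float(self.z[i]),
                "cog_distance_mm": float(self.cog_distance_mm[i]),
                "dice": float(self.dice[i])}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "z_mm": self.z,
            "cog_distance_mm": self.cog_distance_mm,
            "dice": self.dice,
            "defined": np.isfinite(self.cog_distance_mm),
        })


@dataclass
class ValidityResult:
    """Slice COGs against reference nucleus masks at the evaluation levels."""

    levels: Dict[str, Dict[str, float]]
    label: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"level": name, **vals} for name, vals in self.levels.items()]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering and warping
# ---------------------------------------------------------------------------

def render_density(tractogram: Tractogram, shape, affine) -> DensityMap:
    """Count, per voxel, the number of distinct streamlines entering it.

    Each streamline is resampled at half the smallest voxel dimension and
    contributes at most 1 to every voxel it traverses, no matter how often
    it re-enters; points outside the grid contribute nothing.
    """
    affine = np.asarray(affine, dtype=float)
    counts = np.zeros(tuple(shape), dtype=np.int64)
    step = 0.5 * float(voxel_sizes(affine).min())
    for sl in tractogram:
        pts = resample_polyline(sl, step)
        vox = nearest_voxel(affine, pts)
        vox = vox[in_bounds(vox, shape)]
        if len(vox) == 0:
            continue
        uniq = np.unique(vox, axis=0)
        counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    return DensityMap(data=counts, affine=affine, space_tag=tractogram.space_tag,
                      provenance=tractogram.provenance)


def warp_density(density: DensityMap, warp, template_shape=None,
                 template_affine=None) -> DensityMap:
    """Resample a native-space density onto the template grid through a warp.

    ``warp`` is a displacement field on the template grid (see
    :class:`drteval.synthetic_data.WarpField`): each template voxel's value
    is the trilinear sample of the native density at ``template world
    coordinate + displacement``; samples outside the native field are 0.
    """
    disp = np.asarray(warp.displacement, dtype=float)
    t_affine = np.asarray(warp.affine if template_affine is None
                          else template_affine, dtype=float)
    t_shape = tuple(disp.shape[:3]) if template_shape is None else tuple(template_shape)
    if disp.shape[:3] != t_shape or disp.shape[3] != 3:
        raise ValueError(
            f"warp grid {disp.shape} does not match template shape {t_shape}")
    idx = np.indices(t_shape, dtype=float)
    world = np.stack([
        t_affine[a, 0] * idx[0] + t_affine[a, 1] * idx[1]
        + t_affine[a, 2] * idx[2] + t_affine[a, 3] for a in range(3)
    ], axis=-1)
    native_world = world + disp
    inv = np.linalg.inv(density.affine)
    coords = np.stack([
        inv[a, 0] * native_world[..., 0] + inv[a, 1] * native_world[..., 1]
        + inv[a, 2] * native_world[..., 2] + inv[a, 3] for a in range(3)
    ], axis=0)
    out = map_coordinates(density.data, coords.reshape(3, -1), order=1,
                          mode="constant", cval=0.0).reshape(t_shape)
    return DensityMap(data=out, affine=t_affine, space_tag="template",
                      provenance=density.provenance)


# ---------------------------------------------------------------------------
# slice statistics
# ---------------------------------------------------------------------------

def _z_to_slice(affine: np.ndarray, shape, z_level: float) -> int:
    if not is_axis_aligned(affine):
        raise NotImplementedError("slice metrics require an axis-aligned affine")
    k = (z_level - affine[2, 3]) / affine[2, 2]
    ki = int(np.round(k))
    if not 0 <= ki < shape[2]:
        raise ValueError(f"z={z_level} mm maps to slice {ki}, outside volume")
    return ki


def slice_cog(density: DensityMap, z_level: float) -> Optional[Tuple[float, float]]:
    """Mass-weighted mean world (x, y) of the slice nearest to ``z_level``.

    Returns None (undefined) when the slice carries no mass; raises when the
    level falls outside the volume.
    """
    k = _z_to_slice(density.affine, density.data.shape, z_level)
    sl = density.data[:, :, k]
    total = sl.sum()
    if total == 0:
        return None
    ii, jj = np.indices(sl.shape, dtype=float)
    aff = density.affine
    x = aff[0, 0] * ii + aff[0, 1] * jj + aff[0, 2] * k + aff[0, 3]
    y = aff[1, 0] * ii + aff[1, 1] * jj + aff[1, 2] * k + aff[1, 3]
    return (float((sl * x).sum() / total), float((sl * y).sum() / total))


def _check_same_grid(d1: DensityMap, d2: DensityMap) -> None:
    if d1.data.shape != d2.data.shape or not np.allclose(d1.affine, d2.affine,
                                                         atol=1e-6):
        raise ValueError("density maps are not on the same grid")


def cog_distance_profile(d1: DensityMap, d2: DensityMap,
                         params: MetricParams,
                         label: str = "") -> CongruenceResult:
    """Per-z Euclidean distance between the two slice COGs.

    A level is undefined (NaN) when either map has zero mass on the slice;
    aggregates are computed only over defined levels.
    """
    _check_same_grid(d1, d2)
    zs = params.z_levels()
    dist = np.full(len(zs), np.nan)
    for i, z in enumerate(zs):
        c1 = slice_cog(d1, float(z))
        c2 = slice_cog(d2, float(z))
        if c1 is not None and c2 is not None:
            dist[i] = np.hypot(c1[0] - c2[0], c1[1] - c2[1])
    return CongruenceResult(z=zs, cog_distance_mm=dist,
                            dice=np.full(len(zs), np.nan), label=label)


def dice_profile(d1: DensityMap, d2: DensityMap, params: MetricParams,
                 label: str = "") -> CongruenceResult:
    """Per-z Dice of the densities binarised at the streamline threshold.

    ``Dice = 2|A n B| / (|A| + |B|)`` on each slice; undefined when both
    suprathreshold sets are empty there.  ``aggregate()['dice_global']`` is
    not stored; use :func:`congruence_profile` for the combined result.
    """
    _check_same_grid(d1, d2)
    a = d1.data >= params.dice_threshold
    b = d2.data >= params.dice_threshold
    zs = params.z_levels()
    dice = np.full(len(zs), np.nan)
    for i, z in enumerate(zs):
        k = _z_to_slice(d1.affine, d1.data.shape, float(z))
        ak, bk = a[:, :, k], b[:, :, k]
        denom = ak.sum() + bk.sum()
        if denom > 0:
            dice[i] = 2.0 * (ak & bk).sum() / denom
    return CongruenceResult(z=zs, cog_distance_mm=np.full(len(zs), np.nan),
                            dice=dice, label=label)


def whole_range_dice(d1: DensityMap, d2: DensityMap,
                     params: MetricParams) -> float:
    """Dice over the union of all slices in the evaluation range."""
    _check_same_grid(d1, d2)
    ks = sorted({_z_to_slice(d1.affine, d1.data.shape, float(z))
                 for z in params.z_levels()})
    a = d1.data[:, :, ks] >= params.dice_threshold
    b = d2.data[:, :, ks] >= params.dice_threshold
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom > 0 else float("nan")


def congruence_profile(d1: DensityMap, d2: DensityMap, params: MetricParams,
                       label: str = "") -> CongruenceResult:
    """COG-distance and Dice profiles combined into one result."""
    cog = cog_distance_profile(d1, d2, params, label=label)
    dce = dice_profile(d1, d2, params, label=label)
    return CongruenceResult(z=cog.z, cog_distance_mm=cog.cog_distance_mm,
                            dice=dce.dice, label=label)


def validity_cog(density: DensityMap, params: MetricParams,
                 ref_masks: Mapping[str, np.ndarray],
                 label: str = "") -> ValidityResult:
    """Anatomical-validity check of the per-level COG.

    For each evaluation level, the slice COG is tested against that level's
    reference mask (on the same grid): the distance is 0 when the COG's
    voxel lies inside the mask, otherwise the in-plane Euclidean distance to
    the nearest reference voxel centre on that slice.  Levels with an
    undefined COG or an empty reference slice are flagged, not errors.
    """
    levels: Dict[str, Dict[str, float]] = {}
    for name, z in params.eval_levels.items():
        if name not in ref_masks:
            raise KeyError(f"no reference mask for level {name!r}")
        mask = np.asarray(ref_masks[name], dtype=bool)
        if mask.shape != density.data.shape:
            raise ValueError(f"reference mask {name!r} grid mismatch")
        k = _z_to_slice(density.affine, density.data.shape, float(z))
        cog = slice_cog(density, float(z))
        entry: Dict[str, float] = {"z": float(z)}
        if cog is None:
            entry.update(defined=False, inside=False,
                         cog_x=float("nan"), cog_y=float("nan"),
                         distance_mm=float("nan"))
            levels[name] = entry
            continue
        entry.update(defined=True, cog_x=cog[0], cog_y=cog[1])
        msl = mask[:, :, k]
        if not msl.any():
            entry.update(inside=False, distance_mm=float("nan"))
            levels[name] = entry
            continue
        vox = nearest_voxel(density.affine, np.array([[cog[0], cog[1],
                                                       float(z)]]))[0]
        inside = bool(in_bounds(vox[None], density.data.shape)[0]
                      and mask[vox[0], vox[1], k])
        if inside:
            entry.update(inside=True, distance_mm=0.0)
        else:
            ii, jj = np.nonzero(msl)
            centers = voxel_to_world(
                density.affine,
                np.column_stack([ii, jj, np.full(len(ii), k)]).astype(float))
            d = np.hypot(centers[:, 0] - cog[0], centers[:, 1] - cog[1]).min()
            entry.update(inside=False, distance_mm=float(d))
        levels[name] = entry
    return ValidityResult(levels=levels, label=label)
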