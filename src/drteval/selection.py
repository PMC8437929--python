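"""Waypoint selection of DRT streamline candidates.

Implements the automatic selection protocol: a streamline counts as an
uncrossed (DRTu) or crossed (DRTx) dentato-rubro-thalamic tract candidate
when it visits the dentate nucleus of the chosen side, the red nucleus
dilated by 2 mm, and the precentral gyrus, with laterality resolved per
variant.  "Visit" means any resampled point of the streamline falls inside
a mask voxel; termination inside PG can optionally be required.  Manual
elimination of erroneous fibers is emulated deterministically by exclusion
masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt

from ._grid import (in_bounds, nearest_voxel, resample_polyline, voxel_sizes)
from .io_formats import MaskSet, Tractogram

__all__ = [
    "SelectionSpec",
    "resolve_sides",
    "dilate_mask",
    "streamline_visits",
    "select_drt",
    "apply_exclusions",
    "selection_report",
]


@dataclass
class SelectionSpec:
    """Parameters of the DRTu/DRTx waypoint protocol.

    ``laterality`` resolves the anatomically ambiguous wording of which
    hemisphere hosts RN and PG relative to the dentate nucleus:

    * ``"drtx_crosses"`` (default, the textbook decussation): the uncrossed
      variant keeps RN/PG ipsilateral to DN, the crossed variant places them
      contralateral (DRTx traverses the decussation of Wernekinck);
    * ``"drtu_crosses"``: the opposite convention.
    """

    variant: str = "uncrossed"
    dn_side: str = "L"
    rn_dilation_mm: float = 2.0
    require_pg_termination: bool = False
    exclusion_masks: Sequence[str] = field(default_factory=tuple)
    laterality: str = "drtx_crosses"

    def __post_init__(self) -> None:
        if self.variant not in ("uncrossed", "crossed"):
            raise ValueError("variant must be 'uncrossed' or 'crossed'")
        if self.dn_side not in ("L", "R"):
            raise ValueError("dn_side must be 'L' or 'R'")
        if self.rn_dilation_mm < 0:
            raise ValueError("rn_dilation_mm must be >= 0")
        if self.laterality not in ("drtx_crosses", "drtu_crosses"):
            raise ValueError("laterality must be 'drtx_crosses' or 'drtu_crosses'")


def _opp(side: str) -> str:
    return "R" if side == "L" else "L"


def resolve_sides(spec: SelectionSpec) -> Dict[str, str]:
    """Hemisphere of each required waypoint given variant and convention."""
    crossed = (spec.variant == "crossed") == (spec.laterality == "drtx_crosses")
    target = _opp(spec.dn_side) if crossed else spec.dn_side
    return {"DN": spec.dn_side, "RN": target, "PG": target}


def dilate_mask(mask: np.ndarray, radius_mm: float,
                affine: np.ndarray) -> np.ndarray:
    """Dilate a binary mask by a physical radius (world mm).

    A voxel belongs to the output iff its centre lies within ``radius_mm``
    (Euclidean) of some input voxel centre, which handles anisotropic voxels
    correctly; the input is always a subset of the output and the operation
    is monotone in the radius.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    if radius_mm == 0 or not mask.any():
        return mask.copy()
    dist = distance_transform_edt(~mask, sampling=voxel_sizes(affine))
    return dist <= radius_mm + 1e-9


def _visit_step(affine: np.ndarray) -> float:
    return 0.5 * float(voxel_sizes(affine).min())


def _visited_voxels(streamline: np.ndarray, affine: np.ndarray,
                    shape, step: float) -> np.ndarray:
    """Unique in-bounds voxel indices visited by the resampled streamline."""
    pts = resample_polyline(streamline, step)
    vox = nearest_voxel(affine, pts)
    vox = vox[in_bounds(vox, shape)]
    if len(vox) == 0:
        return vox
    return np.unique(vox, axis=0)


def streamline_visits(streamline: np.ndarray, mask: np.ndarray,
                      affine: np.ndarray) -> bool:
    """True iff any resampled point of the streamline falls in a mask voxel.

    The streamline is resampled at half the smallest voxel dimension so a
    coarse point spacing cannot jump over a thin mask.
    """
    mask = np.asarray(mask, dtype=bool)
    vox = _visited_voxels(np.asarray(streamline, float), affine, mask.shape,
                          _visit_step(affine))
    if len(vox) == 0:
        return False
    return bool(mask[vox[:, 0], vox[:, 1], vox[:, 2]].any())


def _required_masks(masks: MaskSet, spec: SelectionSpec) -> Dict[str, np.ndarray]:
    sides = resolve_sides(spec)
    names = {roi: f"{roi}_{side}" for roi, side in sides.items()}
    for roi, name in names.items():
        if name not in masks:
            raise KeyError(f"mask set is missing required mask {name!r}")
    rn = dilate_mask(masks[names["RN"]], spec.rn_dilation_mm, masks.affine)
    return {"DN": masks[names["DN"]], "RN": rn, "PG": masks[names["PG"]]}


def select_drt(tractogram: Tractogram, masks: MaskSet,
               spec: SelectionSpec) -> Tractogram:
    """Retain streamlines that satisfy the DRT waypoint protocol.

    A streamline is kept when it visits DN (on ``dn_side``), the 2-mm
    dilated RN and the PG of the variant's hemisphere; visit order along the
    streamline is not enforced.  With ``require_pg_termination`` one of the
    streamline's endpoints must additionally lie inside PG.  Exclusion masks
    listed in the spec are applied afterwards.  The output is a subset of
    the input and the operation is idempotent.
    """
    req = _required_masks(masks, spec)
    step = _visit_step(masks.affine)
    shape = masks.shape
    kept: List[np.ndarray] = []
    for sl in tractogram:
        vox = _visited_voxels(sl, masks.affine, shape, step)
        if len(vox) == 0:
            continue
        hits = {roi: bool(m[vox[:, 0], vox[:, 1], vox[:, 2]].any())
                for roi, m in req.items()}
        if not all(hits.values()):
            continue
        if spec.require_pg_termination:
            ends = nearest_voxel(masks.affine, sl[[0, -1]])
            ends = ends[in_bounds(ends, shape)]
            if len(ends) == 0 or not req["PG"][ends[:, 0], ends[:, 1],
                                              ends[:, 2]].any():
                continue
        kept.append(sl)
    out = Tractogram(streamlines=kept, space_tag=tractogram.space_tag,
                     provenance=f"{tractogram.provenance}|{spec.variant}_{spec.dn_side}")
    if spec.exclusion_masks:
        out = apply_exclusions(out, [masks[n] for n in spec.exclusion_masks],
                               masks.affine)
    return out


def apply_exclusions(tractogram: Tractogram,
                     exclusion_masks: Iterable[np.ndarray],
                     affine: np.ndarray) -> Tractogram:
    """Remove every streamline that visits any exclusion mask.

    Deterministic stand-in for interactive elimination of erroneous fibers;
    an empty exclusion list is the identity.
    """
    excl = [np.asarray(m, dtype=bool) for m in exclusion_masks]
    if not excl:
        return Tractogram(streamlines=list(tractogram.streamlines),
                          space_tag=tractogram.space_tag,
                          provenance=tractogram.provenance)
    union = np.zeros_like(excl[0], dtype=bool)
    for m in excl:
        union |= m
    kept = [sl for sl in tractogram
            if not streamline_visits(sl, union, affine)]
    return Tractogram(streamlines=kept, space_tag=tractogram.space_tag,
                      provenance=tractogram.provenance)


def selection_report(tractogram: Tractogram, masks: MaskSet,
                     spec: SelectionSpec) -> Dict[str, object]:
    """Per-criterion visit counts for a machine-readable selection report."""
    req = _required_masks(masks, spec)
    step = _visit_step(masks.affine)
    shape = masks.shape
    counts = {roi: 0 for roi in req}
    n_all = 0
    for sl in tractogram:
        vox = _visited_voxels(sl, masks.affine, shape, step)
        if len(vox) == 0:
            continue
        hits = {roi: bool(m[vox[:, 0], vox[:, 1], vox[:, 2]].any())
                for roi, m in req.items()}
        for roi, h in hits.items():
            counts[roi] += int(h)
        n_all += int(all(hits.values()))
    return {
        "variant": spec.variant,
        "dn_side": spec.dn_side,
        "sides": resolve_sides(spec),
        "n_input": len(tractogram),
        "n_visiting": counts,
        "n_selected": n_all,
    }
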