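"""Digital crossing-bundle diffusion phantom with known DRT geometry.

The phantom emulates the acquisition geometry of a clinical single-shell
protocol (b = 1000 s/mm^2, 60 directions, 2 mm isotropic, one b=0) on a 64^3
grid and embeds two tube-shaped fiber bundles whose course mirrors the
schematic dentato-rubro-thalamic anatomy:

* ``drtu`` — the uncrossed variant: dentate nucleus -> superior cerebellar
  peduncle corridor -> red-nucleus-adjacent corridor -> Vim -> precentral
  gyrus, all within one hemisphere;
* ``drtx`` — the crossed variant: same dentate origin, then decussating
  across the midline below the red-nucleus level and ascending the
  contralateral hemisphere through RN, Vim and PG.

Within the decussation the crossed bundle's signal is averaged 50/50 with
the tensor of its midline mirror image (the contralateral crossed tract's
decussation segment), producing genuine crossing-fiber voxels in which a
single-tensor model is inadequate: the principal axis of the mixture is the
bisector of the two fiber axes, so a deterministic tracker with a 20-degree
angulation limit terminates there.  This reproduces, by construction, the
qualitative failure of crossed-tract rendition under deterministic
single-tensor tracking while leaving the uncrossed bundle untouched.

Waypoint masks (DN/RN/PG/SCP/Vim per hemisphere, WM) are placed so the
ground-truth centerlines satisfy the waypoint selection protocol, making the
phantom self-consistent with the analysis it feeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from ._grid import voxel_to_world, world_to_voxel
from .io_formats import DWIVolume, MaskSet
from .selection import dilate_mask

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "WarpField",
    "make_phantom",
    "add_rician_noise",
    "make_warp",
    "make_session_pair",
]


@dataclass
class PhantomSpec:
    """Acquisition and geometry parameters of the synthetic phantom.

    Defaults emulate the low-field clinical protocol the analysis assumes:
    single shell at b = 1000 s/mm^2 with 60 directions plus one b=0, 2 mm
    isotropic voxels on a 64^3 grid.  Bundle tensors are prolate with
    eigenvalues (1.7, 0.3, 0.3) x 1e-3 mm^2/s (FA ~ 0.80); the background is
    isotropic at 0.8e-3 mm^2/s.  ``snr=inf`` is noiseless; finite values add
    Rician noise with sigma = S0 / snr, S0 = 100 arbitrary units.
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 2.0
    n_dirs: int = 60
    b_value: float = 1000.0
    n_b0: int = 1
    bundle_evals: Tuple[float, float, float] = (1.7e-3, 0.3e-3, 0.3e-3)
    background_adc: float = 0.8e-3
    bundle_radius_mm: float = 4.0
    include_crossing: bool = True
    snr: float = math.inf
    seed: int = 0
    s0: float = 100.0
    warp_amplitude_mm: float = 3.0
    warp_max_frequency: int = 2

    def __post_init__(self) -> None:
        l1, l2, l3 = self.bundle_evals
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("bundle eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        if not (self.snr > 0):
            raise ValueError("snr must be positive (inf for noiseless)")
        if self.n_dirs < 6 or self.n_b0 < 1:
            raise ValueError("need >= 6 directions and >= 1 b=0 volume")
        if self.voxel_mm <= 0 or self.bundle_radius_mm <= 0:
            raise ValueError("voxel_mm and bundle_radius_mm must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_mm
        for a in range(3):
            aff[a, 3] = -self.voxel_mm * (self.grid_shape[a] // 2)
        return aff


@dataclass
class WarpField:
    """Template-to-native displacement field.

    ``displacement[i,j,k]`` (mm) is added to the world coordinate of
    template voxel (i,j,k) to reach the corresponding native-space world
    coordinate.  Synthetic fields are smooth low-frequency cosine sums with
    a bounded maximum magnitude.
    """

    displacement: np.ndarray  # (X, Y, Z, 3) mm
    affine: np.ndarray        # template voxel -> world mm

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise ValueError("displacement must have shape (X, Y, Z, 3)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement contains non-finite values")

    def max_magnitude(self) -> float:
        return float(np.linalg.norm(self.displacement, axis=-1).max())


@dataclass
class GroundTruth:
    """Everything the generator knows about the phantom it built."""

    centerlines: Dict[str, np.ndarray]       # world-mm polylines per bundle
    occupancy: Dict[str, np.ndarray]         # boolean tube masks per bundle
    crossing_region: np.ndarray              # boolean, mixed-fiber voxels
    masks: MaskSet                           # waypoint anatomy + WM
    warp: WarpField
    affine: np.ndarray
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

# Control points (world mm on the default 128 mm field of view).  The
# uncrossed bundle stays in the left hemisphere (x < 0); the crossed bundle
# shares the dentate region, decussates around z = -22 and ascends the right
# hemisphere.  Coordinates scale with the field of view for other grids.
_DRTU_POINTS = np.array([
    [-16.0, -16.0, -44.0],   # dentate nucleus (left)
    [-16.0, -13.0, -30.0],
    [-15.0, -10.0, -16.0],   # SCP corridor
    [-14.0, -8.0, -8.0],     # red-nucleus-adjacent corridor
    [-13.0, -4.0, 6.0],      # Vim
    [-14.0, 0.0, 24.0],
    [-16.0, 4.0, 42.0],      # precentral gyrus
])

_DRTX_POINTS = np.array([
    [-16.0, -20.0, -44.0],   # dentate nucleus (left, offset entry)
    [-16.0, -18.0, -36.0],
    [-12.0, -15.0, -29.0],
    [0.0, -12.0, -22.0],     # decussation (midline)
    [12.0, -9.0, -15.0],
    [14.0, -8.0, -8.0],      # red nucleus (right)
    [13.0, -4.0, 6.0],       # Vim (right)
    [14.0, 0.0, 24.0],
    [16.0, 4.0, 42.0],       # precentral gyrus (right)
])

# waypoint boxes: name -> (centre mm, half-extent mm); right-side masks are
# mirrors (x -> -x) of the left ones.
_MASK_BOXES = {
    "DN_L": ((-16.0, -17.0, -42.0), (7.0, 8.0, 7.0)),
    "RN_L": ((-12.0, -8.0, -8.0), (4.0, 4.0, 4.0)),
    "VIM_L": ((-12.0, -4.0, 6.0), (5.0, 5.0, 4.0)),
    "PG_L": ((-16.0, 4.0, 44.0), (8.0, 7.0, 6.0)),
    "SCP_L": ((-16.0, -11.0, -22.0), (5.0, 5.0, 4.0)),
}

_DECUSSATION_HALF_WIDTH_MM = 6.0  # |x| extent of the decussation segment


def _spline_samples(points: np.ndarray, spacing: float = 0.5) -> np.ndarray:
    """Dense samples of a natural cubic spline through the control points."""
    pts = np.asarray(points, dtype=float)
    chord = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    cs = CubicSpline(chord, pts, axis=0)
    n = max(int(np.ceil(chord[-1] / spacing)), 2)
    s = np.linspace(0.0, chord[-1], n + 1)
    return cs(s)


def _tangents(samples: np.ndarray) -> np.ndarray:
    t = np.gradient(samples, axis=0)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _tube_occupancy(samples: np.ndarray, tangents: np.ndarray,
                    centers: np.ndarray, radius: float):
    """Occupancy over voxel `centers`, local fiber tangent and the index of
    the nearest centerline sample."""
    tree = cKDTree(samples)
    dist, idx = tree.query(centers, k=1)
    inside = dist <= radius
    return inside, tangents[idx], idx


def _tensor_quadratic(tangents: np.ndarray, gdirs: np.ndarray,
                      evals: Tuple[float, float, float]) -> np.ndarray:
    """g^T D g for prolate/general tensors with principal axis = tangent.

    For each tangent an orthonormal frame (t, u, v) is built; the quadratic
    form is l1 (g.t)^2 + l2 (g.u)^2 + l3 (g.v)^2.
    """
    l1, l2, l3 = evals
    t = tangents
    ref = np.where(np.abs(t[:, [0]]) < 0.9,
                   np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]]))
    u = np.cross(t, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(t, u)
    gt = t @ gdirs.T
    gu = u @ gdirs.T
    gv = v @ gdirs.T
    return l1 * gt ** 2 + l2 * gu ** 2 + l3 * gv ** 2


def _gradient_table(spec: PhantomSpec):
    """Deterministic single-shell scheme: b=0 volumes then a golden-spiral
    (Fibonacci) point set on the hemisphere, which is near-uniform."""
    n = spec.n_dirs
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - (i + 0.5) / n          # upper hemisphere, avoids antipodes
    r = np.sqrt(np.clip(1.0 - z ** 2, 0.0, 1.0))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvals = np.concatenate([np.zeros(spec.n_b0), np.full(n, spec.b_value)])
    bvecs = np.vstack([np.zeros((spec.n_b0, 3)), dirs])
    return bvals, bvecs


def _check_in_grid(name: str, samples: np.ndarray, spec: PhantomSpec) -> None:
    aff = spec.affine
    lo = voxel_to_world(aff, np.zeros(3)) - spec.voxel_mm / 2
    hi = voxel_to_world(aff, np.asarray(spec.grid_shape, float) - 1) \
        + spec.voxel_mm / 2
    margin = spec.bundle_radius_mm
    bad = np.any((samples < lo + margin) | (samples > hi - margin), axis=1)
    if bad.any():
        p = samples[bad][0]
        raise ValueError(
            f"bundle {name!r} exits the grid at world coordinate "
            f"({p[0]:.1f}, {p[1]:.1f}, {p[2]:.1f}) mm")


def _scaled(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    scale = np.array([s * spec.voxel_mm / 128.0 for s in spec.grid_shape])
    return points * scale


def _box_mask(center, half, centers: np.ndarray, shape) -> np.ndarray:
    inside = np.all(np.abs(centers - np.asarray(center)) <=
                    np.asarray(half) + 1e-9, axis=1)
    return inside.reshape(shape)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def add_rician_noise(signal: np.ndarray, snr: float, seed: int,
                     s0: Optional[float] = None) -> np.ndarray:
    """Apply Rician noise: each value v becomes sqrt((v+n1)^2 + n2^2).

    ``n1, n2 ~ Normal(0, sigma)`` with ``sigma = s0 / snr``; ``s0`` defaults
    to the mean of the first (assumed b=0) volume.  Deterministic for a
    given seed; an infinite SNR returns the input unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if math.isinf(snr):
        return signal.copy()
    if snr <= 0:
        raise ValueError("snr must be positive")
    if s0 is None:
        if signal.ndim != 4:
            raise ValueError("pass s0 explicitly for non-4D input")
        s0 = float(signal[..., 0].mean())
    sigma = s0 / snr
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


def make_warp(template_shape, template_affine, amplitude_mm: float,
              max_frequency: int = 2, n_components: int = 3,
              seed: int = 0) -> WarpField:
    """Smooth random displacement field from a few-component cosine basis.

    Each displacement component is a sum of ``n_components`` plane-wave
    cosines with integer spatial frequencies up to ``max_frequency`` cycles
    per field of view; the field is rescaled so its maximum vector magnitude
    equals ``amplitude_mm`` (zero amplitude yields the zero field).
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    shape = tuple(template_shape)
    disp = np.zeros(shape + (3,))
    if amplitude_mm == 0:
        return WarpField(displacement=disp, affine=np.asarray(template_affine))
    rng = np.random.default_rng(seed)
    u = [np.arange(s) / s for s in shape]
    uu = np.meshgrid(*u, indexing="ij")
    for d in range(3):
        comp = np.zeros(shape)
        for _ in range(n_components):
            freq = rng.integers(1, max_frequency + 1, size=3)
            phase = rng.uniform(0.0, 2.0 * math.pi)
            amp = rng.uniform(0.5, 1.0)
            arg = 2.0 * math.pi * (freq[0] * uu[0] + freq[1] * uu[1]
                                   + freq[2] * uu[2]) + phase
            comp += amp * np.cos(arg)
        disp[..., d] = comp
    mag = np.linalg.norm(disp, axis=-1).max()
    disp *= amplitude_mm / mag
    return WarpField(displacement=disp, affine=np.asarray(template_affine))


def make_phantom(spec: PhantomSpec) -> Tuple[DWIVolume, GroundTruth]:
    """Build the DWI phantom and its ground truth.

    Per voxel the signal is ``S0 * exp(-b g^T D g)`` with the bundle tensor
    (principal axis = local centerline tangent) inside a bundle tube and the
    isotropic background tensor elsewhere; voxels claimed by two fiber
    populations average the two signals 50/50.  Rician noise is applied at
    ``spec.snr`` with ``spec.seed``; identical spec and seed reproduce the
    volume bit for bit.
    """
    shape = tuple(spec.grid_shape)
    aff = spec.affine
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    centers = voxel_to_world(aff, idx)
    bvals, bvecs = _gradient_table(spec)
    gdirs = bvecs[bvals > 0]

    # fiber populations: (occupancy over flat voxels, tangent per voxel)
    populations = {}
    u_samples = _spline_samples(_scaled(_DRTU_POINTS, spec))
    _check_in_grid("drtu", u_samples, spec)
    iu, tu, _ = _tube_occupancy(u_samples, _tangents(u_samples), centers,
                                spec.bundle_radius_mm)
    populations["drtu"] = (iu, tu)
    centerlines = {"drtu": u_samples}
    occupancy = {"drtu": iu.reshape(shape)}
    crossing = np.zeros(shape, dtype=bool)

    if spec.include_crossing:
        x_samples = _spline_samples(_scaled(_DRTX_POINTS, spec))
        _check_in_grid("drtx", x_samples, spec)
        ix, tx, _ = _tube_occupancy(x_samples, _tangents(x_samples), centers,
                                    spec.bundle_radius_mm)
        populations["drtx"] = (ix, tx)
        centerlines["drtx"] = x_samples
        occupancy["drtx"] = ix.reshape(shape)
        # the contralateral crossed tract's decussation segment: the mirror
        # image of drtx, kept only where the mirrored centerline itself lies
        # within the midline band (so it cannot graze the uncrossed bundle)
        m_samples = x_samples * np.array([-1.0, 1.0, 1.0])
        m_tangents = _tangents(m_samples)
        band = _DECUSSATION_HALF_WIDTH_MM * spec.grid_shape[0] \
            * spec.voxel_mm / 128.0
        im, tm, idx_m = _tube_occupancy(m_samples, m_tangents, centers,
                                        spec.bundle_radius_mm)
        im &= np.abs(m_samples[idx_m, 0]) <= band
        populations["decussation_mirror"] = (im, tm)
        crossing = (ix & im).reshape(shape)

    # signal assembly
    n_flat = centers.shape[0]
    att_sum = np.zeros((n_flat, len(gdirs)))
    n_pop = np.zeros(n_flat, dtype=np.int32)
    for inside, tang in populations.values():
        if not inside.any():
            continue
        q = _tensor_quadratic(tang[inside], gdirs, spec.bundle_evals)
        att_sum[inside] += np.exp(-spec.b_value * q)
        n_pop[inside] += 1
    att = np.full((n_flat, len(gdirs)),
                  math.exp(-spec.b_value * spec.background_adc))
    covered = n_pop > 0
    att[covered] = att_sum[covered] / n_pop[covered, None]

    signal = np.concatenate([
        np.full((n_flat, spec.n_b0), spec.s0),
        spec.s0 * att,
    ], axis=1).reshape(shape + (spec.n_b0 + spec.n_dirs,))
    if not math.isinf(spec.snr):
        signal = add_rician_noise(signal, spec.snr, spec.seed, s0=spec.s0)

    # waypoint masks (left boxes + mirrored right boxes) and white matter
    masks: Dict[str, np.ndarray] = {}
    for name, (center, half) in _MASK_BOXES.items():
        c = _scaled(np.asarray(center), spec)
        h = _scaled(np.asarray(half), spec)
        masks[name] = _box_mask(c, h, centers, shape)
        mirrored = c * np.array([-1.0, 1.0, 1.0])
        masks[name.replace("_L", "_R")] = _box_mask(mirrored, h, centers, shape)
    wm = np.zeros(shape, dtype=bool)
    for inside, _ in populations.values():
        wm |= inside.reshape(shape)
    masks["WM"] = dilate_mask(wm, 2.0, aff)
    mask_set = MaskSet(masks={k: v.astype(np.uint8) for k, v in masks.items()},
                       affine=aff)

    warp = make_warp(shape, aff, spec.warp_amplitude_mm,
                     max_frequency=spec.warp_max_frequency,
                     seed=(spec.seed + 90001) % (2 ** 31))

    dwi = DWIVolume(data=signal, affine=aff, bvals=bvals, bvecs=bvecs)
    gt = GroundTruth(centerlines=centerlines, occupancy=occupancy,
                     crossing_region=crossing, masks=mask_set, warp=warp,
                     affine=aff, spec=spec)
    return dwi, gt


def make_session_pair(spec: PhantomSpec) -> Tuple[DWIVolume, DWIVolume, GroundTruth]:
    """Two repeat acquisitions of the same phantom (retest emulation).

    The noiseless signal and ground truth are shared; the sessions carry
    independent Rician noise realisations (seeds ``seed`` and ``seed + 1``).
    With an infinite SNR the two volumes are identical.
    """
    noiseless = replace(spec, snr=math.inf)
    dwi, gt = make_phantom(noiseless)
    if math.isinf(spec.snr):
        dwi2 = DWIVolume(data=dwi.data.copy(), affine=dwi.affine,
                         bvals=dwi.bvals, bvecs=dwi.bvecs)
        return dwi, dwi2, gt
    s1 = add_rician_noise(dwi.data, spec.snr, spec.seed, s0=spec.s0)
    s2 = add_rician_noise(dwi.data, spec.snr, spec.seed + 1, s0=spec.s0)
    a = DWIVolume(data=s1, affine=dwi.affine, bvals=dwi.bvals, bvecs=dwi.bvecs)
    b = DWIVolume(data=s2, affine=dwi.affine, bvals=dwi.bvals, bvecs=dwi.bvecs)
    return a, b, gt
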