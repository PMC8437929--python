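"""Per-voxel diffusion tensor estimation and derived scalar/vector fields.

A standard log-linear least-squares (LLS) single-tensor fit: per voxel the
model ``S_i = S0 * exp(-b_i g_i^T D g_i)`` is linearised as
``ln S_i = ln S0 - b_i g_i^T D g_i`` and solved for the 6 unique tensor
elements plus ``ln S0`` in one batched lstsq over the whole volume.  The
fractional anisotropy (FA) and principal eigenvector fields drive the
deterministic tracker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import DWIVolume

__all__ = ["TensorField", "fit_tensor_lls", "fa"]

_EPS_SIGNAL = 1e-12


@dataclass
class TensorField:
    """Fitted tensor volume plus the derived fields the tracker consumes.

    ``tensors`` are symmetric 3x3 matrices in mm^2/s, ``eigenvalues`` sorted
    descending (negative values clamped to 0), ``e1`` unit principal
    eigenvectors with a fixed sign convention (non-negative x component,
    ties broken on y then z), ``fa`` in [0, 1] and ``valid`` flags voxels
    with a usable fit.
    """

    tensors: np.ndarray      # (X, Y, Z, 3, 3)
    eigenvalues: np.ndarray  # (X, Y, Z, 3) descending
    e1: np.ndarray           # (X, Y, Z, 3)
    fa: np.ndarray           # (X, Y, Z)
    valid: np.ndarray        # (X, Y, Z) bool
    affine: np.ndarray       # (4, 4)

    @property
    def shape(self):
        return self.fa.shape


def fa(eigenvalues: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of eigenvalue triples.

    ``FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||``; invariant under
    permutation and positive scaling of the eigenvalues.  All-zero triples
    give NaN (undefined; callers mark the voxel invalid).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("eigenvalues must have trailing dimension 3")
    if np.any(lam < -1e-12):
        raise ValueError("eigenvalues must be non-negative")
    norm = np.sqrt((lam ** 2).sum(axis=-1))
    dev = lam - lam.mean(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(1.5 * (dev ** 2).sum(axis=-1)) / norm
    out = np.where(norm > 0, out, np.nan)
    return np.clip(out, 0.0, 1.0) if np.ndim(out) else float(np.clip(out, 0.0, 1.0))


def _fix_e1_sign(e1: np.ndarray) -> np.ndarray:
    """Deterministic sign: first non-zero of (x, y, z) made positive."""
    x, y, z = e1[..., 0], e1[..., 1], e1[..., 2]
    sign = np.where(x != 0, np.sign(x), np.where(y != 0, np.sign(y), np.sign(z)))
    sign = np.where(sign == 0, 1.0, sign)
    return e1 * sign[..., None]


def fit_tensor_lls(dwi: DWIVolume) -> TensorField:
    """Batched log-linear least-squares single-tensor fit.

    Requires at least 6 diffusion-weighted directions spanning the unique
    tensor elements and at least one b=0 volume.  Voxels with non-positive
    signal anywhere, a non-positive fitted S0, or a non-finite fit are
    marked invalid; negative eigenvalues are clamped to 0 before computing
    FA.
    """
    bvals, bvecs = dwi.bvals, dwi.bvecs
    dw = bvals > 0
    if dw.sum() < 6:
        raise ValueError(f"need >=6 diffusion-weighted directions, got {int(dw.sum())}")
    g = bvecs
    # design: ln S = [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]
    #                @ [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]
    B = np.column_stack([
        np.ones_like(bvals),
        -bvals * g[:, 0] ** 2,
        -bvals * g[:, 1] ** 2,
        -bvals * g[:, 2] ** 2,
        -2 * bvals * g[:, 0] * g[:, 1],
        -2 * bvals * g[:, 0] * g[:, 2],
        -2 * bvals * g[:, 1] * g[:, 2],
    ])
    if np.linalg.matrix_rank(B) < 7:
        raise ValueError("gradient directions are collinear/degenerate for a tensor fit")

    shape = dwi.data.shape[:3]
    signal = dwi.data.reshape(-1, dwi.n_volumes)
    bad_signal = (signal <= 0).any(axis=1) | ~np.isfinite(signal).all(axis=1)
    logS = np.log(np.clip(signal, _EPS_SIGNAL, None))
    coef, *_ = np.linalg.lstsq(B, logS.T, rcond=None)  # (7, nvox)
    coef = coef.T
    ln_s0 = coef[:, 0]

    D = np.empty((signal.shape[0], 3, 3))
    D[:, 0, 0] = coef[:, 1]
    D[:, 1, 1] = coef[:, 2]
    D[:, 2, 2] = coef[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = coef[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = coef[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = coef[:, 6]

    valid = np.isfinite(coef).all(axis=1) & np.isfinite(ln_s0) & ~bad_signal
    D[~valid] = np.eye(3) * 1e-9  # placeholder; flagged invalid

    evals, evecs = np.linalg.eigh(D)          # ascending
    evals = evals[:, ::-1]                     # descending
    evecs = evecs[:, :, ::-1]
    evals_c = np.clip(evals, 0.0, None)
    e1 = _fix_e1_sign(np.ascontiguousarray(evecs[:, :, 0]))

    fa_flat = fa(evals_c)
    valid &= np.isfinite(fa_flat)
    fa_flat = np.where(valid, fa_flat, 0.0)

    return TensorField(
        tensors=D.reshape(shape + (3, 3)),
        eigenvalues=evals_c.reshape(shape + (3,)),
        e1=e1.reshape(shape + (3,)),
        fa=fa_flat.reshape(shape),
        valid=valid.reshape(shape),
        affine=dwi.affine.copy(),
    )
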