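"""Shared fixtures: phantoms and hand-built tensor fields."""

import numpy as np
import pytest

from drteval import PhantomSpec, make_phantom, fit_tensor_lls
from drteval.tensor_model import TensorField


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default noiseless crossing phantom (64^3 @ 2 mm, 60 dirs, b=1000)."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_field(noiseless_phantom):
    dwi, _ = noiseless_phantom
    return fit_tensor_lls(dwi)


def make_uniform_field(shape=(24, 24, 24), voxel=2.0, direction=(1.0, 0.0, 0.0),
                       fa_value=0.8):
    """Tensor field with one constant principal direction everywhere."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = -voxel * (np.array(shape) // 2)
    l1, l2 = 1.7e-3, 0.3e-3
    D = l2 * np.eye(3) + (l1 - l2) * np.outer(d, d)
    tensors = np.broadcast_to(D, shape + (3, 3)).copy()
    e1 = np.broadcast_to(d, shape + (3,)).copy()
    evals = np.broadcast_to(np.array([l1, l2, l2]), shape + (3,)).copy()
    return TensorField(
        tensors=tensors, eigenvalues=evals, e1=e1,
        fa=np.full(shape, fa_value), valid=np.ones(shape, dtype=bool),
        affine=affine,
    )


def make_split_field(shape=(40, 24, 24), voxel=2.0, angle_deg=30.0,
                     fa_value=0.8):
    """Field whose direction rotates by `angle_deg` (in xy) at the mid-x plane."""
    field = make_uniform_field(shape, voxel, (1.0, 0.0, 0.0), fa_value)
    a = np.radians(angle_deg)
    d2 = np.array([np.cos(a), np.sin(a), 0.0])
    half = shape[0] // 2
    l1, l2 = 1.7e-3, 0.3e-3
    D2 = l2 * np.eye(3) + (l1 - l2) * np.outer(d2, d2)
    field.e1[half:] = d2
    field.tensors[half:] = D2
    return field
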