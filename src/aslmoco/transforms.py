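"""Rigid-body resampling of 3D volumes on regular, possibly anisotropic grids.

Conventions
-----------
A rigid transform is parameterised by a 6-vector ``(tx, ty, tz, rx, ry, rz)``
with translations in millimetres and rotations in degrees.  Rotations are
right-handed and applied in the order ``rx -> ry -> rz`` about the geometric
centre of the voxel grid; the translation is added afterwards, in world
(millimetre) coordinates.  World coordinates are ``(index - centre) * voxel``
along each array axis, i.e. axis 0 = x, axis 1 = y, axis 2 = z (slices).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["rotation_matrix", "rigid_world_matrix", "apply_rigid", "apply_rigid_inverse"]

_INTERP_ORDER = {"trilinear": 1, "spline": 3}


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """3x3 right-handed rotation matrix from degrees, applied rx -> ry -> rz."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    r_x = np.array([[1.0, 0.0, 0.0], [0.0, cx, -sx], [0.0, sx, cx]])
    r_y = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    r_z = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    return r_z @ r_y @ r_x


def rigid_world_matrix(params: np.ndarray) -> np.ndarray:
    """Homogeneous 4x4 world-space matrix for a 6-parameter rigid transform."""
    params = np.asarray(params, dtype=float)
    if params.shape != (6,):
        raise ValueError(f"rigid parameters must be a 6-vector, got shape {params.shape}")
    if not np.all(np.isfinite(params)):
        raise ValueError("rigid parameters must be finite")
    mat = np.eye(4)
    mat[:3, :3] = rotation_matrix(*params[3:])
    mat[:3, 3] = params[:3]
    return mat


def _voxel_to_world(shape, voxel_size) -> np.ndarray:
    centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    vox = np.asarray(voxel_size, dtype=float)
    if vox.shape != (3,) or np.any(vox <= 0):
        raise ValueError("voxel_size must be 3 positive lengths in mm")
    mat = np.eye(4)
    mat[:3, :3] = np.diag(vox)
    mat[:3, 3] = -centre * vox
    return mat


def _resample(volume: np.ndarray, world: np.ndarray, voxel_size, interp: str,
              mode: str = "constant") -> np.ndarray:
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    try:
        order = _INTERP_ORDER[interp]
    except KeyError:
        raise ValueError(f"unknown interpolation {interp!r}; use 'trilinear' or 'spline'") from None
    vox2world = _voxel_to_world(volume.shape, voxel_size)
    # output voxel -> output world -> input world (inverse transform) -> input voxel
    amat = np.linalg.inv(vox2world) @ np.linalg.inv(world) @ vox2world
    return ndimage.affine_transform(
        volume, amat[:3, :3], offset=amat[:3, 3], order=order,
        mode=mode, cval=0.0, prefilter=order > 1)


def apply_rigid(volume: np.ndarray, params, voxel_size, interp: str = "trilinear",
                mode: str = "constant") -> np.ndarray:
    """Move ``volume`` by the rigid transform ``params``.

    The anatomy is displaced *forward*: a positive ``tz`` shifts tissue towards
    larger slice indices.  Voxels mapped from outside the field of view are
    zero-filled (``mode='constant'``).
    """
    return _resample(volume, rigid_world_matrix(params), voxel_size, interp, mode)


def apply_rigid_inverse(volume: np.ndarray, params, voxel_size,
                        interp: str = "trilinear", mode: str = "constant") -> np.ndarray:
    """Resample ``volume`` with the inverse of the transform ``params``.

    This undoes :func:`apply_rigid` up to interpolation error and is the
    reslicing operation used after motion estimation.
    """
    world = np.linalg.inv(rigid_world_matrix(params))
    return _resample(volume, world, voxel_size, interp, mode)
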