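"""Rigid-body motion correction of 4D ASL series (framework step 2).

Each dynamic is registered independently to a reference volume — either the
M0 calibration image (free of BGS dark lines) or the first acquired ASL
dynamic — by derivative-free (Powell) minimisation of an image-dissimilarity
cost over the six rigid parameters, on a two-level coarse-to-fine pyramid
(in-plane downsampling only, so that through-plane intensity structure such
as BGS dark lines is preserved at both levels).

The module also builds the two auxiliary 4D data sets the perfusion GLM
needs: the "resliced BGS effect" (per-slice homogenization factors expanded
to a volume and resampled with each dynamic's estimated motion) and the
post-MoCo residual-error series (homogenized series after minus before
reslicing).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .homogenize import BGSProfile
from .phantom_sim import MotionTrace
from .transforms import apply_rigid_inverse

__all__ = [
    "RegistrationOptions", "RegistrationResult", "ReslicedBGSEffect",
    "register_rigid", "moco_series", "reslice_with_trace",
    "make_resliced_bgs_effect", "residual_error_series",
]

log = logging.getLogger(__name__)


@dataclass
class RegistrationOptions:
    """Knobs of the rigid registration.

    cost : 'ncc' — negative normalized correlation, optionally augmented with a
        low-order polynomial intensity gain along the slice axis
        (``z_gain_order``).  The smooth gain absorbs slowly varying intensity
        modulation (e.g. residual homogenization trends) without hiding sharp
        slice-to-slice structure such as BGS dark lines.
    z_gain_order : polynomial order of the slice-direction gain (0 = plain NCC).
    coarse_maxiter / fine_maxiter : Powell iteration caps per pyramid level.
    xtol, ftol : Powell convergence tolerances (fine level; the coarse level
        uses 5x the parameter tolerance).
    smooth_z : Gaussian sigma (voxels) applied to both images along the slice
        axis before the cost; de-emphasises sub-slice structure and the
        fractional-shift interpolation blur that otherwise biases
        through-plane estimates.
    cache_identical : reuse the estimate for byte-identical dynamics (noise-free
        simulated series repeat volumes within a motion plateau).
    """

    cost: str = "ncc"
    z_gain_order: int = 2
    coarse_maxiter: int = 3
    fine_maxiter: int = 2
    xtol: float = 0.01
    ftol: float = 1e-6
    smooth_sigma_inplane: float = 1.0
    smooth_z: float = 0.5
    max_translation_mm: float = 20.0
    max_rotation_deg: float = 15.0
    zero_motion_threshold: float = 0.4
    cache_identical: bool = True


@dataclass
class RegistrationResult:
    trace: MotionTrace
    cost_history: np.ndarray
    reference_id: str
    converged: np.ndarray

    def __post_init__(self):
        if len(self.trace) != self.cost_history.size:
            raise ValueError("trace and cost history lengths differ")


@dataclass
class ReslicedBGSEffect:
    """4D expansion of the per-slice BGS factors, resampled per dynamic."""

    data: np.ndarray

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("resliced BGS effect must be 4D")


# ---------------------------------------------------------------------------
# single-volume registration
# ---------------------------------------------------------------------------

def _downsample_inplane(vol: np.ndarray, sigma: float) -> np.ndarray:
    sm = ndimage.gaussian_filter(vol, sigma=(sigma, sigma, 0.0))
    return np.ascontiguousarray(sm[::2, ::2, :])


class _CostLevel:
    """One pyramid level: prefiltered moving volume, cropped reference and cost."""

    def __init__(self, moving: np.ndarray, reference: np.ndarray, voxel_size,
                 options: RegistrationOptions):
        from .transforms import _voxel_to_world, rigid_world_matrix

        self._rigid_world_matrix = rigid_world_matrix
        self.options = options
        ref = reference
        if options.smooth_z > 0:
            # both images are blurred identically along z so the cost neither
            # favours integer-slice shifts nor keys on sub-slice structure
            ref = ndimage.gaussian_filter(ref, (0.0, 0.0, options.smooth_z))
            moving = ndimage.gaussian_filter(moving.astype(np.float32),
                                             (0.0, 0.0, options.smooth_z))
        support = ndimage.binary_dilation(ref > 0.05 * ref.max(), iterations=2)
        # crop the cost evaluation to the reference support bounding box
        sl = ndimage.find_objects(support.astype(np.int8))[0]
        self.origin = np.array([s.start for s in sl], dtype=float)
        self.out_shape = tuple(s.stop - s.start for s in sl)
        self.sup = support[sl]
        self.ref_vals = ref[sl][self.sup].astype(np.float64)
        fc = self.ref_vals - self.ref_vals.mean()
        self.sst = float(fc @ fc)
        self.movf = ndimage.spline_filter(moving.astype(np.float32), order=3)
        self.v2w = _voxel_to_world(moving.shape, voxel_size)
        # normalized world-z coordinate of every support voxel, for the z-gain
        nz = moving.shape[2]
        zn = (np.arange(sl[2].start, sl[2].stop) - (nz - 1) / 2.0) / max((nz - 1) / 2.0, 1.0)
        zvol = np.broadcast_to(zn[None, None, :], self.out_shape)
        self.z_powers = [zvol[self.sup] ** k for k in range(1, options.z_gain_order + 1)]
        self._ones = np.ones(self.ref_vals.size)

    def resample(self, params: np.ndarray) -> np.ndarray:
        mat = np.linalg.inv(self.v2w) @ self._rigid_world_matrix(params) @ self.v2w
        amat = mat[:3, :3]
        offset = mat[:3, 3] + amat @ self.origin
        return ndimage.affine_transform(self.movf, amat, offset=offset,
                                        output_shape=self.out_shape, order=3,
                                        prefilter=False, cval=0.0)

    def cost(self, params: np.ndarray) -> float:
        r = self.resample(params)[self.sup].astype(np.float64)
        cols = [self._ones, r] + [r * zp for zp in self.z_powers]
        a = np.stack(cols, axis=1)
        beta, *_ = np.linalg.lstsq(a, self.ref_vals, rcond=None)
        resid = self.ref_vals - a @ beta
        ssr = float(resid @ resid)
        if self.sst == 0:
            return 0.0
        return -float(np.sqrt(max(1.0 - ssr / self.sst, 0.0)))


def register_rigid(moving: np.ndarray, reference: np.ndarray, voxel_size,
                   options: Optional[RegistrationOptions] = None,
                   x0: Optional[np.ndarray] = None):
    """Estimate the 6-parameter rigid motion of ``moving`` relative to ``reference``.

    Returns ``(params, cost, converged)`` where ``params`` is the motion such
    that resampling ``moving`` with its inverse aligns it with ``reference``.
    Deterministic for fixed inputs and options.
    """
    if options is None:
        options = RegistrationOptions()
    if options.cost != "ncc":
        raise ValueError(f"unknown cost {options.cost!r}")
    if moving.shape != reference.shape:
        raise ValueError("moving and reference must share one grid")
    if np.ptp(reference) == 0:
        raise ValueError("reference volume is constant")

    vox = np.asarray(voxel_size, dtype=float)
    mov32 = np.asarray(moving, dtype=np.float32)
    ref32 = np.asarray(reference, dtype=np.float32)

    levels = []
    if min(moving.shape[:2]) >= 32:
        sig = options.smooth_sigma_inplane
        levels.append((_downsample_inplane(mov32, sig), _downsample_inplane(ref32, sig),
                       vox * np.array([2.0, 2.0, 1.0]),
                       options.coarse_maxiter, options.xtol * 5))
    levels.append((mov32, ref32, vox, options.fine_maxiter, options.xtol))

    params = np.zeros(6) if x0 is None else np.asarray(x0, dtype=float).copy()
    bounds = ([(-options.max_translation_mm, options.max_translation_mm)] * 3
              + [(-options.max_rotation_deg, options.max_rotation_deg)] * 3)
    converged = True
    cost = np.inf
    for mov, ref, lvox, maxiter, xtol in levels:
        level = _CostLevel(mov, ref, lvox, options)
        res = optimize.minimize(level.cost, params, method="Powell", bounds=bounds,
                                options={"maxiter": maxiter, "xtol": xtol,
                                         "ftol": options.ftol})
        params = np.asarray(res.x, dtype=float)
        cost = float(res.fun)
        converged = bool(res.success) or res.status == 1  # status 1 = maxiter reached
    return params, cost, converged


# ---------------------------------------------------------------------------
# series-level operations
# ---------------------------------------------------------------------------

def moco_series(series: np.ndarray, reference: np.ndarray, voxel_size,
                options: Optional[RegistrationOptions] = None,
                reference_id: str = "m0", reslice: bool = True,
                reslice_interp: str = "spline"):
    """Register every dynamic of a 4D series to ``reference`` and reslice.

    Returns ``(RegistrationResult, resliced_series)``; ``resliced_series`` is
    ``None`` when ``reslice=False`` (estimation-only runs).  Dynamics with
    byte-identical data reuse one estimate when ``options.cache_identical``.
    """
    if options is None:
        options = RegistrationOptions()
    series = np.asarray(series)
    if series.ndim != 4:
        raise ValueError("series must be 4D (x, y, z, dynamic)")
    n = series.shape[3]
    trace = np.zeros((n, 6))
    costs = np.zeros(n)
    flags = np.zeros(n, dtype=bool)
    cache: dict[str, tuple] = {}
    for d in range(n):
        vol = series[..., d]
        key = None
        if options.cache_identical:
            key = hashlib.md5(np.ascontiguousarray(vol, dtype=np.float32).tobytes()).hexdigest()
            if key in cache:
                trace[d], costs[d], flags[d] = cache[key]
                continue
        params, costs[d], flags[d] = register_rigid(vol, reference, voxel_size, options)
        # estimates below the registration's own precision floor are noise;
        # applying them would only inject interpolation error into the series
        params[np.abs(params) < options.zero_motion_threshold] = 0.0
        trace[d] = params
        if key is not None:
            cache[key] = (trace[d].copy(), costs[d], flags[d])
        if not flags[d]:
            log.warning("registration of dynamic %d did not converge; best-so-far kept", d)

    result = RegistrationResult(trace=MotionTrace(trace), cost_history=costs,
                                reference_id=reference_id, converged=flags)
    resliced = reslice_with_trace(series, result.trace, voxel_size,
                                  interp=reslice_interp) if reslice else None
    return result, resliced


def reslice_with_trace(volume4d: np.ndarray, trace: MotionTrace, voxel_size,
                       interp: str = "spline") -> np.ndarray:
    """Resample each dynamic into reference space with the inverse of its motion."""
    volume4d = np.asarray(volume4d)
    if volume4d.ndim != 4:
        raise ValueError("expected a 4D volume")
    if volume4d.shape[3] != len(trace):
        raise ValueError("trace length does not match the series")
    out = np.empty_like(volume4d, dtype=float)
    for d in range(volume4d.shape[3]):
        if np.any(trace[d] != 0):
            out[..., d] = apply_rigid_inverse(volume4d[..., d], trace[d], voxel_size, interp)
        else:
            out[..., d] = volume4d[..., d]
    return out


def make_resliced_bgs_effect(profile: BGSProfile, trace: MotionTrace, shape,
                             voxel_size, interp: str = "trilinear") -> ReslicedBGSEffect:
    """Expand per-slice BGS factors to 4D and reslice each dynamic with its motion.

    The per-slice-constant volume is resampled with nearest-edge padding so
    the regressor stays positive at the volume borders.
    """
    shape = tuple(shape)
    if len(shape) != 3 or shape[2] != len(profile):
        raise ValueError("grid shape inconsistent with the BGS profile")
    base = np.broadcast_to(profile.factors[None, None, :], shape).astype(float)
    n = len(trace)
    out = np.empty(shape + (n,))
    cache: dict[tuple, np.ndarray] = {}
    for d in range(n):
        key = tuple(np.round(trace[d], 9))
        if key not in cache:
            if np.any(trace[d] != 0):
                cache[key] = apply_rigid_inverse(base, trace[d], voxel_size,
                                                 interp=interp, mode="nearest")
            else:
                cache[key] = base
        out[..., d] = cache[key]
    return ReslicedBGSEffect(data=out)


def residual_error_series(homog_before: np.ndarray, homog_after_moco: np.ndarray) -> np.ndarray:
    """Post-MoCo error regressor: homogenized series after minus before reslicing."""
    before = np.asarray(homog_before)
    after = np.asarray(homog_after_moco)
    if before.shape != after.shape:
        raise ValueError("before/after series shapes differ")
    return after - before
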