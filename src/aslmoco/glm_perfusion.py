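"""Voxelwise GLM extraction of perfusion signal (framework step 3).

The unsubtracted, homogenized and realigned ASL time series at each voxel is
regressed onto

* a constant baseline column (the homogenized static-tissue signal),
* a perfusion column: the alternating labeling paradigm [+0.5, -0.5, ...]
  multiplied by the motion-resliced BGS effect at that voxel, which both
  undoes the perfusion-signal scaling introduced by homogenization and tracks
  tissue that moved through slices with different suppression levels,
* optionally an activation column (labeling x activation blocks x resliced
  BGS effect) for functional ASL, and
* optionally the post-MoCo residual-error regressor.

``beta_perf`` is the perfusion-weighted (delta-M) map; the t-statistic of
``beta_act_perf`` maps activation.  Estimation is ordinary least squares with
homoscedastic variance per voxel; note the design matrix is voxel-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .rigid_moco import ReslicedBGSEffect

__all__ = ["Paradigm", "OLSFit", "FitResult", "build_voxel_design", "ols_fit", "fit_series"]

# an error column with norm below this fraction of the data norm is dropped
# per voxel to avoid rank deficiency (no-motion voxels)
_ERROR_NORM_REL_TOL = 1e-8


@dataclass
class Paradigm:
    """Labeling paradigm (+0.5 control / -0.5 label) and optional activation blocks."""

    labeling: np.ndarray
    activation_blocks: Optional[np.ndarray] = None
    block_duration_s: Optional[float] = None

    def __post_init__(self):
        self.labeling = np.asarray(self.labeling, dtype=float)
        if self.labeling.ndim != 1:
            raise ValueError("labeling must be a per-dynamic vector")
        expected = np.where(np.arange(self.labeling.size) % 2 == 0, 0.5, -0.5)
        if self.labeling[0] != 0.5 or not np.array_equal(self.labeling, expected):
            raise ValueError("labeling must alternate [+0.5, -0.5, ...] starting with control")
        if self.activation_blocks is not None:
            self.activation_blocks = np.asarray(self.activation_blocks, dtype=float)
            if self.activation_blocks.shape != self.labeling.shape:
                raise ValueError("activation blocks must match the labeling length")

    @classmethod
    def alternating(cls, n_dynamics: int, activation_blocks=None,
                    block_duration_s=None) -> "Paradigm":
        lab = np.where(np.arange(n_dynamics) % 2 == 0, 0.5, -0.5)
        return cls(lab, activation_blocks=activation_blocks, block_duration_s=block_duration_s)

    def __len__(self) -> int:
        return self.labeling.size


@dataclass
class OLSFit:
    betas: np.ndarray
    se: np.ndarray
    t: np.ndarray
    resid_var: float
    dof: int
    names: list


@dataclass
class FitResult:
    """Voxel maps of the GLM coefficients and statistics."""

    beta_baseline: np.ndarray
    beta_perf: np.ndarray
    t_perf: np.ndarray
    se_perf: np.ndarray
    resid_var: np.ndarray
    dof: int
    mask: np.ndarray
    beta_act_perf: Optional[np.ndarray] = None
    t_act_perf: Optional[np.ndarray] = None
    beta_error: Optional[np.ndarray] = None
    error_dropped: Optional[np.ndarray] = None


def build_voxel_design(paradigm: Paradigm, resliced_bgs_voxel=None, error_voxel=None):
    """Assemble the voxel-specific design matrix.

    Returns ``(X, names, error_dropped)``.  ``resliced_bgs_voxel`` defaults to
    unity (plain subtraction design); an all-zero error column is dropped.
    """
    n = len(paradigm)
    if resliced_bgs_voxel is None:
        bgs = np.ones(n)
    else:
        bgs = np.asarray(resliced_bgs_voxel, dtype=float)
        if bgs.shape != (n,):
            raise ValueError("resliced BGS values must match the paradigm length")
    cols = [np.ones(n), paradigm.labeling * bgs]
    names = ["baseline", "perf"]
    if paradigm.activation_blocks is not None:
        cols.append(paradigm.labeling * paradigm.activation_blocks * bgs)
        names.append("act_perf")
    error_dropped = False
    if error_voxel is not None:
        err = np.asarray(error_voxel, dtype=float)
        if err.shape != (n,):
            raise ValueError("error regressor must match the paradigm length")
        if np.linalg.norm(err) > 0:
            cols.append(err)
            names.append("error")
        else:
            error_dropped = True
    return np.column_stack(cols), names, error_dropped


def design_to_csv(design: np.ndarray, names, path) -> None:
    """Export one voxel's design matrix as CSV for audit."""
    import pandas as pd

    pd.DataFrame(np.asarray(design), columns=list(names)).to_csv(path, index_label="dynamic")


def ols_fit(y: np.ndarray, design, names=None) -> OLSFit:
    """Ordinary least squares for one voxel; t = beta / SE with dof = n - p."""
    y = np.asarray(y, dtype=float)
    if isinstance(design, tuple):
        design, names = design[0], design[1]
    x = np.asarray(design, dtype=float)
    n, p = x.shape
    if y.shape != (n,):
        raise ValueError("y length does not match the design")
    dof = n - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    betas, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    resid = y - x @ betas
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, betas / se, 0.0)
    return OLSFit(betas=betas, se=se, t=t, resid_var=sigma2, dof=dof,
                  names=list(names) if names is not None else [f"b{i}" for i in range(p)])


def _batched_ols(y: np.ndarray, x: np.ndarray):
    """OLS over a batch of voxel-specific designs.

    y : (v, t), x : (v, t, p).  Returns betas (v, p), se (v, p), sigma2 (v,).
    """
    xtx = np.einsum("vti,vtj->vij", x, x)
    xty = np.einsum("vti,vt->vi", x, y)
    try:
        betas = np.linalg.solve(xtx, xty[..., None])[..., 0]
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        v, _, p = x.shape
        betas = np.empty((v, p))
        xtx_inv = np.empty((v, p, p))
        for i in range(v):
            xtx_inv[i] = np.linalg.pinv(xtx[i])
            betas[i] = xtx_inv[i] @ xty[i]
    resid = y - np.einsum("vtp,vp->vt", x, betas)
    dof = x.shape[1] - x.shape[2]
    sigma2 = np.einsum("vt,vt->v", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2[:, None] * np.einsum("vpp->vp", xtx_inv), 0.0))
    return betas, se, sigma2


def fit_series(series: np.ndarray, resliced_bgs, paradigm: Paradigm,
               error_series: Optional[np.ndarray] = None,
               mask: Optional[np.ndarray] = None) -> FitResult:
    """Fit the voxelwise GLM over a 4D series.

    ``resliced_bgs`` may be a :class:`ReslicedBGSEffect`, a 4D array, or
    ``None`` for a unit (plain subtraction) scaling.  Per-voxel failures do
    not abort the volume: an (all but) zero-norm error column is dropped for
    that voxel and flagged in ``error_dropped``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be 4D (x, y, z, dynamic)")
    shape3, n = series.shape[:3], series.shape[3]
    if len(paradigm) != n:
        raise ValueError("paradigm length does not match the series")
    if isinstance(resliced_bgs, ReslicedBGSEffect):
        bgs4d = resliced_bgs.data
    elif resliced_bgs is None:
        bgs4d = None
    else:
        bgs4d = np.asarray(resliced_bgs, dtype=float)
    if bgs4d is not None and bgs4d.shape != series.shape:
        raise ValueError("resliced BGS effect shape does not match the series")
    if error_series is not None and error_series.shape != series.shape:
        raise ValueError("error series shape does not match the series")
    if mask is None:
        mask = np.ones(shape3, dtype=bool)

    idx = np.flatnonzero(mask.ravel())
    y = series.reshape(-1, n)[idx]
    bgs = bgs4d.reshape(-1, n)[idx] if bgs4d is not None else np.ones_like(y)
    lab = paradigm.labeling

    cols = [np.ones_like(y), lab[None, :] * bgs]
    names = ["baseline", "perf"]
    has_act = paradigm.activation_blocks is not None
    if has_act:
        cols.append((lab * paradigm.activation_blocks)[None, :] * bgs)
        names.append("act_perf")
    has_err = error_series is not None
    if has_err:
        err = np.asarray(error_series, dtype=float).reshape(-1, n)[idx]
        keep = np.linalg.norm(err, axis=1) > _ERROR_NORM_REL_TOL * np.linalg.norm(y, axis=1)
    p_base = len(cols)

    nvox = y.shape[0]
    p_full = p_base + (1 if has_err else 0)
    betas = np.full((nvox, p_full), np.nan)
    se = np.full((nvox, p_full), np.nan)
    sigma2 = np.full(nvox, np.nan)
    x_base = np.stack(cols, axis=2)  # (v, t, p_base)

    if has_err:
        if np.any(keep):
            xk = np.concatenate([x_base[keep], err[keep][:, :, None]], axis=2)
            b, s, v = _batched_ols(y[keep], xk)
            betas[keep], se[keep], sigma2[keep] = b, s, v
        if np.any(~keep):
            b, s, v = _batched_ols(y[~keep], x_base[~keep])
            betas[~keep, :p_base], se[~keep, :p_base], sigma2[~keep] = b, s, v
        dof = n - p_full
    else:
        b, s, v = _batched_ols(y, x_base)
        betas[:, :p_base], se[:, :p_base], sigma2[:] = b, s, v
        dof = n - p_base
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")

    def _vol(col):
        out = np.zeros(shape3)
        out.ravel()[idx] = col
        return out

    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, betas / se, 0.0)

    result = FitResult(
        beta_baseline=_vol(betas[:, 0]),
        beta_perf=_vol(betas[:, 1]),
        t_perf=_vol(tvals[:, 1]),
        se_perf=_vol(se[:, 1]),
        resid_var=_vol(sigma2),
        dof=dof,
        mask=mask.copy(),
    )
    col = 2
    if has_act:
        result.beta_act_perf = _vol(betas[:, col])
        result.t_act_perf = _vol(tvals[:, col])
        col += 1
    if has_err:
        err_col = np.where(keep, betas[:, col], np.nan)
        result.beta_error = _vol(np.nan_to_num(err_col))
        dropped = np.zeros(shape3, dtype=bool)
        dropped.ravel()[idx] = ~keep
        result.error_dropped = dropped
    return result
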