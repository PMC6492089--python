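"""Slice-wise background-suppression homogenization (framework step 1).

The per-slice BGS effect is the ratio of the mean tissue value of the M0
calibration image to the mean tissue value of the BGS-ASL series (pooled over
all dynamics) in that slice.  Multiplying every slice of the series by its
factor equalises the static-tissue signal across slices, removing the "BGS
dark lines" that otherwise bias rigid realignment and cause subtraction
errors under through-plane motion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["BGSProfile", "default_tissue_mask", "estimate_bgs_effect", "apply_homogenization"]

log = logging.getLogger(__name__)


@dataclass
class BGSProfile:
    """Per-slice positive scale factors and the tissue mask used to estimate them."""

    factors: np.ndarray
    mask_used: np.ndarray | None = None
    source: str = ""

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.ndim != 1:
            raise ValueError("factors must be a per-slice 1D array")
        if not np.all(np.isfinite(self.factors)) or np.any(self.factors <= 0):
            raise ValueError("BGS factors must be finite and positive")

    def __len__(self) -> int:
        return self.factors.size

    def to_json(self) -> str:
        return json.dumps({"source": self.source,
                           "factors": {str(z): f for z, f in enumerate(self.factors)}})

    @classmethod
    def from_json(cls, text: str) -> "BGSProfile":
        obj = json.loads(text)
        items = sorted(obj["factors"].items(), key=lambda kv: int(kv[0]))
        return cls(np.array([v for _, v in items]), source=obj.get("source", ""))


def default_tissue_mask(m0: np.ndarray) -> np.ndarray:
    """Otsu threshold on the M0 image followed by in-plane morphological closing."""
    from skimage.filters import threshold_otsu

    thr = threshold_otsu(np.asarray(m0, dtype=float))
    mask = m0 > thr
    return ndimage.binary_closing(mask, structure=np.ones((3, 3, 1), dtype=bool))


def estimate_bgs_effect(series: np.ndarray, m0: np.ndarray,
                        mask: np.ndarray | None = None) -> BGSProfile:
    """Estimate the per-slice BGS effect from an ASL series and its M0 image.

    ``factors[z]`` is the mean of M0 over the tissue mask in slice ``z``
    divided by the mean of the series over the same voxels and *all* dynamics.
    A slice with no tissue voxels inherits the factor of the nearest valid
    slice (with a logged warning); a non-positive slice mean signals corrupt
    input and is rejected.
    """
    series = np.asarray(series)
    if series.ndim != 4:
        raise ValueError("series must be 4D (x, y, z, dynamic)")
    if m0.shape != series.shape[:3]:
        raise ValueError("m0 grid does not match the series")
    if mask is None:
        mask = default_tissue_mask(m0)
    if mask.shape != m0.shape:
        raise ValueError("mask grid does not match the series")

    nz = series.shape[2]
    factors = np.full(nz, np.nan)
    for z in range(nz):
        sel = mask[:, :, z]
        if not np.any(sel):
            continue
        num = float(np.mean(m0[:, :, z][sel]))
        den = float(np.mean(series[:, :, z, :][sel, :]))
        if den <= 0 or num <= 0:
            raise ValueError(f"non-positive mean tissue value in slice {z}; corrupt input")
        factors[z] = num / den

    missing = np.isnan(factors)
    if np.all(missing):
        raise ValueError("tissue mask is empty in every slice")
    if np.any(missing):
        valid = np.flatnonzero(~missing)
        for z in np.flatnonzero(missing):
            nearest = valid[np.argmin(np.abs(valid - z))]
            factors[z] = factors[nearest]
            log.warning("slice %d has no tissue voxels; using factor of slice %d", z, nearest)

    return BGSProfile(factors=factors, mask_used=mask)


def apply_homogenization(series: np.ndarray, profile: BGSProfile) -> np.ndarray:
    """Multiply every slice of every dynamic by its BGS-effect factor."""
    series = np.asarray(series)
    if series.ndim != 4:
        raise ValueError("series must be 4D (x, y, z, dynamic)")
    if len(profile) != series.shape[2]:
        raise ValueError(f"profile has {len(profile)} slices, series has {series.shape[2]}")
    return series * profile.factors[None, None, :, None]
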