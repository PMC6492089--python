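"""CBF quantification with the single-compartment white-paper model.

CBF (mL/100 g/min) from the perfusion-weighted signal delta-M:

    CBF = 6000 * lambda * dM * exp(PLD / T1b)
          / (2 * alpha * T1b * M0 * (1 - exp(-tau / T1b)))

with T1b in seconds so the factor 6000 yields mL/100 g/min.  The M0
calibration image acquired at a short TR is first corrected for incomplete
T1 recovery by the factor 1 / (1 - exp(-TR / T1_gm)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["QuantParams", "correct_m0", "cbf_map"]


@dataclass
class QuantParams:
    """White-paper quantification constants.

    lambda_ : brain-blood partition coefficient (mL/g).
    t1_blood_ms : longitudinal relaxation time of arterial blood.
    alpha : labeling efficiency.
    tau_ms / pld_ms : labeling duration and post-labeling delay.
    m0_tr_ms / t1_gm_ms : TR of the M0 scan and assumed grey-matter T1 for
        the incomplete-recovery correction.
    """

    lambda_: float = 0.95
    t1_blood_ms: float = 1650.0
    alpha: float = 0.85
    tau_ms: float = 1800.0
    pld_ms: float = 1800.0
    m0_tr_ms: float = 2500.0
    t1_gm_ms: float = 1200.0

    def __post_init__(self):
        for name in ("lambda_", "t1_blood_ms", "alpha", "tau_ms", "pld_ms",
                     "m0_tr_ms", "t1_gm_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha > 1.0:
            raise ValueError("labeling efficiency alpha must be in (0, 1]")


def correct_m0(m0: np.ndarray, tr_ms: float, t1_gm_ms: float) -> np.ndarray:
    """Scale a short-TR M0 image by 1 / (1 - exp(-TR / T1_gm))."""
    if tr_ms <= 0 or t1_gm_ms <= 0:
        raise ValueError("TR and T1 must be positive")
    factor = 1.0 / (1.0 - np.exp(-tr_ms / t1_gm_ms))
    return np.asarray(m0, dtype=float) * factor


def cbf_map(dm: np.ndarray, m0_corrected: np.ndarray, params: QuantParams,
            mask: np.ndarray, slice_offsets_ms: Optional[np.ndarray] = None) -> np.ndarray:
    """Voxelwise CBF (mL/100 g/min) from a delta-M map and corrected M0.

    ``slice_offsets_ms`` optionally increments the effective PLD per slice by
    its acquisition offset (multi-slice readout); by default a single PLD is
    used.  Voxels with non-positive M0 are zeroed.
    """
    dm = np.asarray(dm, dtype=float)
    m0c = np.asarray(m0_corrected, dtype=float)
    if dm.shape != m0c.shape or dm.shape != mask.shape:
        raise ValueError("dm, m0 and mask must share one grid")
    t1b_s = params.t1_blood_ms / 1000.0
    pld_ms = np.full(dm.shape[2], params.pld_ms)
    if slice_offsets_ms is not None:
        offsets = np.asarray(slice_offsets_ms, dtype=float)
        if offsets.shape != (dm.shape[2],):
            raise ValueError("slice offsets must have one value per slice")
        pld_ms = pld_ms + offsets
    scale = (6000.0 * params.lambda_ * np.exp((pld_ms / 1000.0) / t1b_s)
             / (2.0 * params.alpha * t1b_s * (1.0 - np.exp(-(params.tau_ms / 1000.0) / t1b_s))))
    eps = 1e-6 * np.max(np.abs(m0c)) if np.max(np.abs(m0c)) > 0 else 1.0
    valid = mask & (m0c > eps)
    out = np.zeros_like(dm)
    out[valid] = (dm[valid] / m0c[valid]) * np.broadcast_to(scale[None, None, :], dm.shape)[valid]
    return out
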