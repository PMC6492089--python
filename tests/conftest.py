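"""Shared fixtures.

The heavyweight fixtures (motion-estimation comparison, perfusion-separation
comparison, functional run) are session-scoped and reuse each other's motion
estimates wherever two pipeline variants share a registration stage, so the
suite performs each rigid registration exactly once.
"""

import numpy as np
import pytest

from aslmoco import AcquisitionSpec, build_phantom, fourstep_motion
from aslmoco.evaluate import run_fmri, run_sim1, run_sim2

# study conditions of the synthetic evaluation (fixed; see docs/methods.md)
PHANTOM_SEED = 7
N_DYNAMICS = 20
FMRI_N_DYNAMICS = 44
FMRI_NOISE_SD = 0.1
FMRI_SEED = 11
FMRI_GAIN = 0.6


@pytest.fixture(scope="session")
def phantom64():
    return build_phantom((64, 64, 18), (3.0, 3.0, 7.0), seed=PHANTOM_SEED)


@pytest.fixture(scope="session")
def phantom_small():
    return build_phantom((32, 32, 12), (3.0, 3.0, 7.0), seed=3)


@pytest.fixture(scope="session")
def acq20():
    return AcquisitionSpec(n_dynamics=N_DYNAMICS)


@pytest.fixture(scope="session")
def acq_small():
    return AcquisitionSpec(n_slices=12, sms_factor=3, n_dynamics=8)


@pytest.fixture(scope="session")
def sim1_results(phantom64, acq20):
    """Registration-variant comparison on through-plane axes plus one in-plane."""
    return run_sim1(phantom64, acq20, axes=("tz", "rx", "ry", "tx"))


@pytest.fixture(scope="session")
def mocoD_traces(phantom64, acq20, sim1_results):
    """MoCo-D motion estimates for all six stepwise patterns."""
    extra = run_sim1(phantom64, acq20, axes=("ty", "rz"), variants=("MoCo-D",))
    traces = {ax: sim1_results[ax]["traces"]["MoCo-D"] for ax in ("tx", "tz", "rx", "ry")}
    traces.update({ax: extra[ax]["traces"]["MoCo-D"] for ax in ("ty", "rz")})
    return traces


@pytest.fixture(scope="session")
def sim2_results(phantom64, acq20, sim1_results):
    """Pipeline comparison for through-plane (tz, rx) and in-plane (tx) motion.

    Registration stages are reused from the variant comparison: NewMoCo shares
    the MoCo-D estimate and StdMoCo the MoCo-B estimate of the same series.
    """
    out = {}
    for axis in ("tz", "rx", "tx"):
        pre = {"NewMoCo": sim1_results[axis]["traces"]["MoCo-D"],
               "StdMoCo": sim1_results[axis]["traces"]["MoCo-B"]}
        out[axis] = run_sim2(phantom64, acq20, axis, precomputed_traces=pre)
    return out


@pytest.fixture(scope="session")
def fmri_results(phantom64):
    acq = AcquisitionSpec(n_dynamics=FMRI_N_DYNAMICS)
    motion = fourstep_motion("tz", 4.2, 8.4, FMRI_N_DYNAMICS)
    blocks = ((np.arange(FMRI_N_DYNAMICS) // 8) % 2).astype(float)
    return run_fmri(phantom64, acq, motion, blocks, activation_gain=FMRI_GAIN,
                    noise_sd=FMRI_NOISE_SD, seed=FMRI_SEED)
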