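# aslmoco

Motion correction and perfusion extraction for **background-suppressed (BGS)
arterial spin labeling (ASL)** perfusion MRI acquired with **simultaneous
multi-slice (SMS) EPI**, together with a Bloch-equation digital phantom that
makes the whole method testable without any scanner data.

## The problem

ASL measures cerebral blood flow (CBF) by subtracting magnetically *labeled*
from *control* images; the tiny difference signal ΔM rides on a large static
tissue background, which BGS inversion pulses suppress. With a 2D SMS-EPI
readout, slices excited later recover more longitudinal magnetisation, so the
suppression level varies slice-to-slice — and because SMS interleaves slice
groups, slices with the strongest suppression sit directly next to slices
with the weakest ("BGS dark lines"). Two failure modes follow when the
subject moves through-plane:

1. **Mis-registration** — rigid realignment locks onto the dark lines instead
   of the anatomy, so motion is under-estimated.
2. **BGS subtraction errors** — even after perfect realignment, tissue that
   moved between slices experienced *different* suppression in control and
   label, leaving static-tissue residuals that dwarf ΔM.

## The correction framework

1. **Homogenize** (`aslmoco.homogenize`): estimate the per-slice BGS effect

   `BGS_effect(z) = mean tissue value of slice z of M0 / mean tissue value of
   slice z of the BGS-ASL series (all dynamics)`

   and multiply each slice by it, flattening the dark lines.
2. **Realign** (`aslmoco.rigid_moco`): six-parameter rigid registration of
   every dynamic to the M0 calibration image (which has no dark lines), then
   reslice.  The per-slice factors are also expanded into a 4D volume and
   resliced with the same motion — the *resliced BGS effect*.
3. **Extract perfusion** (`aslmoco.glm_perfusion`): voxelwise GLM of the
   unsubtracted series

   `y_t = β_baseline·1 + β_perf·(x_label,t · BGS_effect_resliced) +
   [β_act·(x_label,t · block_t · BGS_effect_resliced)] + β_error·x_error,t + e_t`

   where `x_label = [+0.5, −0.5, …]` is the control/label alternation and
   `x_error` is the homogenized series *after minus before* reslicing — a
   surrogate for residual BGS subtraction errors.  `β_perf` is the
   perfusion-weighted ΔM map; the t-statistic of `β_act` maps activation in
   functional ASL.
4. **Quantify** (`aslmoco.quantify`): single-compartment white-paper model,

   `CBF = 6000·λ·ΔM·exp(PLD/T1b) / (2·α·T1b·M0·(1 − exp(−τ/T1b)))`

   with λ = 0.95 mL/g, T1b = 1650 ms, α = 0.85, τ = PLD = 1800 ms, and the
   short-TR M0 correction `1/(1 − exp(−TR/T1_gm))`.

`aslmoco.phantom_sim` builds the digital head phantom and simulates the
BGS-SMS acquisition with injected rigid motion and left-hemisphere-only
perfusion (the perfusion-free right hemisphere measures artefacts);
`aslmoco.evaluate` reproduces the evaluation statistics (normalized mean
difference of motion estimates, artefact CDFs, ROI t-statistics) for the
pipeline variants *NewMoCo*, *StdMoCo*, *NoMoCo*, *NewMoCo_wo_error_reg* and
the registration variants *MoCo-A/B/C/D*.

## Worked example

```python
import numpy as np
from aslmoco import (AcquisitionSpec, Paradigm, build_phantom, fourstep_motion,
                     simulate_asl_series, run_pipeline)

phantom = build_phantom((64, 64, 18), (3.0, 3.0, 7.0), seed=7)
acq = AcquisitionSpec(n_dynamics=20)          # 18 slices, SMS 3, BGS at 1860/3150 ms
motion = fourstep_motion("rx", 3.0, 6.0, 20)  # stepwise +-3 / +-6 deg about x
series = simulate_asl_series(phantom, acq, motion)

paradigm = Paradigm.alternating(acq.n_dynamics)
new = run_pipeline(series, phantom.m0, "NewMoCo", paradigm)
std = run_pipeline(series, phantom.m0, "StdMoCo", paradigm)

right = phantom.mask & (np.arange(64)[:, None, None] > 31)   # perfusion-free
for name, res in [("NewMoCo", new), ("StdMoCo", std)]:
    p95 = np.percentile(np.abs(res.cbf[right]), 95)
    print(f"{name}: 95th pct |CBF| in perfusion-free hemisphere = {p95:.1f} mL/100g/min")
```

prints:

```
NewMoCo: 95th pct |CBF| in perfusion-free hemisphere = 17.3 mL/100g/min
StdMoCo: 95th pct |CBF| in perfusion-free hemisphere = 88.5 mL/100g/min
```

No perfusion was simulated in the right hemisphere, so any signal there is a
processing artefact: conventional M0-referenced motion correction (*StdMoCo*)
leaves BGS subtraction errors comparable to cortical CBF itself (~90
mL/100g/min), while the full framework (*NewMoCo*) suppresses them by roughly
an order of magnitude.

A command-line interface mirrors the library:

```bash
aslmoco simulate --motion-axis tz --out sim/
aslmoco homogenize --series sim/asl.nii.gz --m0 sim/m0.nii.gz --out hom/
aslmoco moco --series hom/homogenized.nii.gz --reference m0 --m0 sim/m0.nii.gz --out moco/
aslmoco evaluate --experiment sim2 --out results/
```

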