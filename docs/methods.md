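# Methods

This note records the model, the simulation design, the numerical choices
and the known limitations of `aslmoco`, in the order the pipeline runs.

## Signal model and phantom

The phantom is an ellipsoidal head on a 64×64×18 grid of 3×3×7 mm voxels:
a CSF rim, a grey-matter shell and a white-matter core whose interfaces are
modulated by low-order angular harmonics (gyrification-like structure —
without it the ellipsoid is too close to rotationally symmetric for
rotations to be observable by intensity-based registration). Literature 3T
values are used: T1 = 1200 / 800 / 4000 ms and relative proton density
0.8 / 0.7 / 1.0 for GM / WM / CSF (M0 scaled to 100). M0 carries a smooth
±5 % multiplicative bias field (the only seeded randomness in the phantom)
and is smoothed by σ = 0.6 voxel in all three axes — in-plane point spread
plus the partial-volume averaging of a 7 mm slice profile. The T1 and label
maps stay crisp. The outer brain mask is a plain ellipsoid, mirror-symmetric
in x. Perfusion-weighted amplitude ΔM = 1 % of the local M0 is assigned to
left-hemisphere GM only (x < 0), so the right hemisphere is a perfusion-free
artefact meter. The brain fills ~80 % of the slice stack, leaving headroom
for ±8.4 mm through-plane motion without content leaving the field of view.

Background suppression is modelled by piecewise integration of the
longitudinal Bloch equation, `Mz(t) = M0(1−e^{−t/T1}) + Mz(0)e^{−t/T1}`,
across a presaturation (Mz→0) at t = 0 (the start of labeling) and
inversions (Mz→−Mz) at 1860 and 3150 ms. The readout of the first SMS
excitation starts at τ + PLD = 3600 ms; with 18 slices, SMS factor 3 and a
30 ms inter-excitation interval, slices {z, z+6, z+12} share excitation
z mod 6 at 3600 + 30·(z mod 6) ms (ascending order — suppression is best for
the first group). The per-voxel attenuation factor is Mz/M0 evaluated with
that voxel's T1 at its slice's readout time; with these timings GM
attenuates to 0.045 in the first group and 0.157 in the last, producing the
characteristic 3.5× "dark line" contrast at group boundaries.

Each simulated dynamic moves the anatomy (M0, T1, ΔM maps) rigidly *first*
and evaluates the attenuation from the *moved* T1 map afterwards, so tissue
experiences the suppression of the slice it currently occupies — the only
order that produces BGS subtraction errors. Label dynamics (even 1-based
numbers) subtract the moved ΔM, scaled by (1 + activation gain) inside
activation blocks; images are stored as magnitude. Optional Gaussian noise
(default 0) is seeded.

### Motion design

Stepwise single-axis motion with four equal plateaus at +small, −small,
+large, −large; defaults ±4.2/±8.4 mm for translations and ±3/±6° for
rotations. With an odd number of dynamics per plateau every step falls
*between a control acquisition and its label partner* — motion "during
labeling and/or PLD, never during a readout". This matters: if each
control/label pair shared one motion state, the static suppression change
would be orthogonal to the alternating labeling regressor and no BGS
subtraction error would reach β_perf at all. Rotations are right-handed,
applied rx→ry→rz about the grid centre, translations added in mm afterwards.

## Homogenization

Per-slice factors are the ratio of M0 slice means to series slice means
(all dynamics pooled) over a tissue mask (Otsu threshold on M0 + in-plane
morphological closing; an explicit mask can be supplied). Slices without
tissue inherit the nearest valid factor with a logged warning. Perfusion
contaminates the slice means by construction; on the default phantom the
factors deviate from the pure static-tissue inverse attenuation by < 2 %.

## Rigid registration

Each dynamic is registered independently to the reference (M0 by default)
by bounded Powell search (±20 mm, ±15°) over the six rigid parameters on a
two-level pyramid (in-plane downsampling ×2 only, preserving through-plane
structure; iteration caps 3 coarse / 2 fine, parameter tolerance 0.01).
The cost is a negative normalized correlation computed over the dilated
reference support, with two refinements that matter at 7 mm slice thickness:

* the moving image is resampled with a cubic B-spline (prefiltered once per
  level) and both images are pre-blurred by σ = 0.5 voxel along z; without
  this, the asymmetry between fractional-slice and integer-slice
  interpolation blur biases through-plane estimates toward integer shifts
  by up to ~1 mm, and cross-contrast sub-slice structure adds a spurious
  ~1 mm tz offset when registering BGS data to M0;
* the correlation admits a multiplicative intensity gain that is quadratic
  in z. Homogenization factors estimated from a motion-corrupted series
  leave a slowly varying z-modulation on the static signal; the smooth gain
  absorbs it, while the sharp sawtooth of the BGS dark lines cannot be
  absorbed — so registration of *unhomogenized* data against a dark-lined
  reference still fails in exactly the way the framework is designed to
  expose. (Normalized mutual information was evaluated as an alternative
  and rejected: its discrete joint histogram creates spurious local minima
  under subvoxel resampling on these smooth synthetic images.)

Byte-identical dynamics (noise-free plateaus) share one estimate. Final
reslicing uses cubic-spline interpolation; optimisation resampling is
independent of it. On the default phantom the residual bias of the
homogenized-vs-M0 registration is below ~0.2 mm / 0.2° on the moved axis
and ~0.3 mm on unmoved axes. Per-parameter estimates below 0.4 mm / 0.4° —
the measured precision floor of this cost on 3×3×7 mm voxels — are treated
as no motion: applying sub-precision estimates only injects interpolation
noise, and the slight control-versus-label difference in such estimates
(the perfusion deficit perturbs the optimizer path) is labeling-correlated
and would leak into β_perf through the error regressor.

## GLM

Per voxel, ordinary least squares of the unsubtracted series on: constant
baseline; labeling alternation [+0.5, −0.5, …] × resliced BGS effect;
optionally labeling × activation boxcar × resliced BGS effect (no
hemodynamic convolution); optionally the error regressor (homogenized
series after − before reslicing), dropped per voxel when its norm is below
1e−8 of the data norm (flagged). Homoscedastic variance, t = β/SE with
dof = n − p; no autocorrelation modelling, no spatial smoothing, no
multiple-testing correction (raw t > 3.0 is the activation threshold).
With unit BGS scaling and even n the estimator reduces exactly to the mean
of pairwise control−label differences.

## Quantification

Single-compartment white-paper model with λ = 0.95 mL/g, T1,blood =
1650 ms, α = 0.85, τ = PLD = 1800 ms; T1 values converted to seconds so the
6000 factor yields mL/100 g/min. The M0 image is pre-scaled by
1/(1 − exp(−TR/T1_gm)) with TR = 2500 ms, T1_gm = 1200 ms. A flag enables
per-slice effective PLD (adding each slice's acquisition offset); default
off — a single PLD, as the model is usually quoted.

## Evaluation design and problem sizes

* *Motion-estimation comparison* (20 dynamics per series): variants MoCo-A
  (raw series, first-dynamic reference), -B (raw, M0), -C (homogenized,
  first dynamic), -D (homogenized, M0). Scored by the normalized mean
  difference — mean absolute per-dynamic parameter error on the moved axis,
  divided by the larger plateau magnitude (8.4 mm or 6°) — against the
  estimate from a BGS- and perfusion-free twin series with identical
  motion, registered with the *same* reference choice, so that generic
  registration error (and the baseline position of the first dynamic)
  cancels. Ground-truth comparisons are reported alongside.
* *Perfusion-separation comparison* (20 dynamics): pipelines NewMoCo
  (homogenize → M0-referenced MoCo → GLM with resliced-BGS scaling and
  error regressor), StdMoCo (M0-referenced MoCo only, plain subtraction
  GLM), NoMoCo (homogenized, unrealigned GLM), NewMoCo_wo_error_reg.
  Metrics: empirical CDF and 95th percentile of |CBF| in the eroded right
  hemisphere; RMS of (CBF − motion-free reference) over the GM/WM boundary
  band (one dilation from each side of the interface).
* *Functional run* (44 dynamics, 8-dynamic activation blocks, gain 0.6,
  stepwise tz ±4.2/±8.4 mm, Gaussian noise SD 0.1 ≈ 0.13 % of GM M0): ROI =
  ground-truth activated region dilated by one voxel; reported are mean t
  of the activation coefficient and the count of ROI voxels with t > 3.

These sizes keep a full evaluation to a few minutes on one CPU while every
plateau still spans multiple control/label pairs; they are the package's
default study conditions.

## What the phantom does and does not show

The simulation reproduces the mechanism of interest — slice-dependent
suppression interacting with through-plane motion — with exact ground
truth, but it omits EPI distortion, water–fat shift, physiological noise,
T2*/readout effects, spatially varying labeling efficiency, intra-readout
motion and non-rigid deformation. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms, and the *direction*
of the pipeline comparisons, not in-vivo effect sizes. Known limitations:
very large motion at the strongest dark line can still defeat the slicewise
homogenization (the error regressor is a surrogate, not a model); the
registration carries the residual biases quoted above; and slices near the
top/bottom of the stack with little tissue inherit neighbouring
homogenization factors.
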