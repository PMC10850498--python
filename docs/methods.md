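# Methods

## The measurement model

The sample vibrates periodically at the acoustic stimulation frequency
*f* (default 128 Hz, period T = 7.8125 ms). One stimulation cycle is
divided into *N* equal phase windows (default 10, width T/N = 0.78125 ms);
window 0 starts at an ascending zero crossing of the gating sine. Each
reconstructed phase volume is treated as a snapshot of the sample within
its window. Every ossicle is modelled as a rigid body: its configuration at
phase j relative to phase 0 is a rotation matrix Rⱼ plus translation tⱼ
about a stated origin, and a point x (relative to that origin) moves to
Rⱼx + tⱼ. All internal computation is in voxel units; reported lengths are
converted through the voxel size (default 2.75 µm).

## Phase gating

A frame with exposure-start timestamp tᵢ belongs to window
⌊frac((tᵢ − t_ref)·f)·N⌋. Numerically this is evaluated as
`((t − t_ref) mod T) // (T/N)`: for the canonical 2 kHz clock against
128 Hz both T and T/N are binary-representable, so frames that sit exactly
on a window boundary (every 25th frame) are binned exactly; the naive
`frac(Δt·f)` route multiplies by an inexact 0.128 and mis-assigns a few
hundred of them. The exposure-start (not mid-exposure) time is used for
binning, matching trigger semantics; frames whose exposure straddles a
boundary are kept (the 0.495 ms exposure is well under the 0.78 ms window).
All frames are kept, including those of an incomplete final cycle.

Zero-crossing detection on a sampled gating trace takes the first
ascending sign change and interpolates linearly between the bracketing
samples.

## Phase-time convention

Ground truth, gating and sine fitting all attribute window j to its START
time j·T/N. This makes the phase-0 transform exactly the identity (phase 0
is the registration reference, so anything else would be inconsistent) and
makes the generator's transform sequence exactly the prescribed sinusoid at
the window times. A window-CENTER convention ((j+0.5)·T/N) is available via
the `phase_time` switch in both the phantom spec and the run config;
because generation and fitting share the convention, parameter recovery is
self-consistent under either choice, and ground truth is always expressed
relative to phase 0.

## The phantom generator

Each body is one of four shapes (capsule, L-prism, arch, ellipsoid) with a
frozen low-pass-filtered Gaussian random texture (correlation length
≈ 1.8 voxels, contrast 0.35 about a base intensity of 1.0) inside a
softened mask. The texture plays the role of the ossicles' internal
vascular structure: a uniform body would leave rotation about its symmetry
axes unobservable to any intensity metric. Motion is sinusoidal per body —
angle(s) = A_rot·sin(2π(s + offset)) about a fixed axis through the body
center, translation componentwise with the same temporal phase — with
defaults in the study regime: rotations up to 2°, translations up to
3 voxels, 10 phases, 2.75 µm voxels. Rendering resamples the rest template
through the inverse pose with cubic splines (sub-voxel motion must be
representable), on a per-body subgrid so the spline prefilter's
exponentially decaying ringing stays local and background voxels are
bitwise identical across phases. A static textured spherical shell stands
in for the surrounding temporal bone. Noise is additive Gaussian only;
SNR is quoted as body intensity / noise σ (σ = 0.05 → SNR 20). Ring
artifacts, beam physics, reconstruction streaks and intensity drift are
NOT emulated — passing recovery tests bounds algorithmic error, not
detector- or reconstruction-induced error on real data.

A body whose rotated bounding box would leave the grid (with a 2-voxel
spline margin) at any phase is rejected up front, naming the body and
phase.

## Registration

Per sub-volume and phase, SimpleITK's rigid registration
(Euler3DTransform centred at the SV center) aligns the phase-0 crop to the
phase-j crop: Mattes mutual information (50 bins) or normalized
cross-correlation, regular-step gradient descent with learning rate 0.5,
relaxation 0.5, minimum step 1e-5, at most 1000 iterations, three pyramid
levels (shrink 4/2/1, smoothing 2/1/0), linear interpolation, identity
initialization (motions are a few voxels at most), crops z-scored before
metric evaluation. The optimizer's gradient-magnitude tolerance is lowered
to 1e-8: with physical-shift parameter scaling the metric gradient is tiny
near the optimum, and the library default stops a step early, leaving
~0.1–1° of rotation unresolved on small crops. The fitted resampling
transform (fixed = p₀, moving = pⱼ) equals the forward motion p₀→pⱼ of the
imaged content, so it is stored as-is. NCC is the default in phantom
pipelines (mono-modal data, better conditioned on small crops); MI is
retained for mixed-contrast use. Convergence is recorded per registration;
hitting the iteration cap flags the transform rather than failing the run.

Measured accuracy on noiseless 64-voxel crops: ≤ ~0.02 voxel and ~0.03°
for motions in the study range; at SNR 10, translation error stays below
0.06 voxel (≈ 0.17 µm), comfortably sub-voxel.

## Averaging and outlier rejection

All SV transforms of an ossicle are re-expressed at the center of its
first SV (the global origin) using t⁽⁰⁾ = t⁽ⁱ⁾ + (R − I)(O₀ − O⁽ⁱ⁾), which
leaves the induced point mapping exactly invariant. Seven parameters per SV
— three translation components, three axis components (sign-aligned to the
largest-angle SV), the angle — are vetted in two stages: first any
|value| > 5×|median| discards the SV (the signature of a non-converged
registration), then any deviation beyond 2σ of the survivors' mean
discards it. The ordering matters: a non-converged outlier would inflate σ
and hide itself from the 2σ rule if both were applied to the raw
distribution. With n = 4–8 SVs a genuine density fit is meaningless, so
"Gaussian center" is operationalized as the sample mean. Fewer than 3 SVs
cannot be vetted: all pass with a warning. Rejection is per phase by
default (an SV may fail at one phase and serve at another); a whole-SV
mode is available. Zero-variance parameters discard nothing.

Survivors average component-wise: translation as vectors, axes
sign-aligned then averaged and renormalized, the angle as a scalar, and
the mean rotation matrix is rebuilt from the mean axis-angle. This is the
stated component-wise scheme, not a proper rotation mean
(quaternion/chordal); for the sub-2° rotations here the two differ at
O(θ²) ≈ 1e-3 degrees, far below registration noise. Per-parameter sample
standard deviations are the error bars.

The principal rotation axis is the angle-weighted, sign-aligned mean of
per-phase axes, excluding phases whose angle is below 10% of the cycle
maximum (near the motion's zero crossings the axis direction is pure
noise) and renormalizing. Axis colinearity between ossicles is measured as
arccos|a·b| ∈ [0°, 90°].

## Displacement and sine fitting

ROI points move through the per-phase mean transforms; displacements are
point-averaged (the spread across points measures sensitivity to the
manual selection). The per-phase displacement norm gets the sign of its
projection on the unit displacement at the phase of maximum norm, so
collinear oscillations become clean signed sinusoids instead of rectified
ones. The reference direction is arbitrary up to sign: flipping it negates
the series and shifts φ by exactly half a cycle, leaving A and R²
unchanged — φ should therefore be compared only under a shared reference.

The constrained sine D(t) = A·sin(2π(f·t + φ)) has fixed f, so it is
linear in (a, b) = (A·cos2πφ, A·sin2πφ): the fit is a closed-form
least-squares solve on the sin/cos basis — deterministic and global, no
initialization. A ≥ 0 and φ ∈ [0,1) are canonicalized via
(−A, φ) ≡ (A, φ+½). R² = 1 − SS_res/SS_tot about the series mean; an
identically-zero series is defined to fit perfectly (R² = 1). Amplitude
ratios between stimulation conditions are A_high/A_low, aggregated as the
arithmetic mean of per-sample ratios.

The noise floor runs the identical pipeline on a region known to be
static and reports its maximal apparent translation, rotation and induced
point displacement over phases. Configured bounds default to 0.2 µm /
0.002° / 0.3 µm — sub-voxel-regime figures appropriate to large
experimental sub-volumes; phantom-scale SVs (≈ 20 voxels) resolve rotation
more coarsely, so phantom runs compare against the induced-displacement
figure, the quantity that matters downstream. Fitted amplitudes below the
measured floor are flagged unreliable in the run log.

## Planar QC

Profile matrices sample a fixed line in every phase volume with linear
interpolation (default 1-voxel spacing). The extreme shift is the largest
sub-sample lag over all phase pairs, from cross-correlating profile
GRADIENTS (a bare edge yields a flat correlation plateau; its gradient is
a localized peak) with parabolic refinement of the integer peak, times the
sample spacing and voxel size. The standard-deviation projection uses the
sample (n−1) standard deviation across phases — with n = 10 the n vs n−1
choice is material and is stated here.

## Problem sizes

Tests and the acceptance script use 64–96³ grids, 10 phases, bodies of
15–25 voxel half-extent, 2–3 SVs of 16–32 voxel extent per body, and
SNR 10–20 — sizes at which one registration takes ~1 s and the full
three-body recovery about half a minute on one CPU, while amplitudes,
phases and angle profiles are still recovered within a few percent.
The full acquisition arithmetic (40,000 frames) is always computed exactly.

## Known limitations

- Rigid bodies only; no deformable registration, no intra-ossicle strain.
- No screw-axis (helical) decomposition; rotation + translation are
  reported about the chosen origin, so the translation component depends
  on that origin (the induced point motion does not).
- The phantom's noise model omits structured artifacts (rings, streaks),
  so recovery results bound algorithmic error only.
- Component-wise rotation averaging assumes small angles (fine below a few
  degrees; do not reuse for large rotations).
- The displacement sign convention is one consistent choice among several;
  absolute φ values are only comparable under a shared reference direction.
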