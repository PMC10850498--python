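# ossimotion

Motion analysis for retrospectively gated dynamic microtomography of the
middle-ear ossicular chain.

When the ear is driven by a pure tone (e.g. 128 Hz), the eardrum and the
three ossicles — malleus, incus, stapes — vibrate with micrometre
amplitudes. Dynamic synchrotron microtomography captures this by acquiring
tens of thousands of projection frames over many stimulation cycles while
the sample slowly rotates, then retrospectively sorting the frames into
phase windows of the cycle and reconstructing one 3D volume per phase.
`ossimotion` implements everything downstream of (and independent of) the
tomographic reconstruction:

- **postgating** — assign each frame to one of *N* phase windows from the
  camera exposure timestamps and the gating sine's ascending zero crossing:
  `phase(i) = floor(frac((tᵢ − t_ref)·f)·N)`; plus flat/dark-field
  correction and per-phase occupancy/angular-coverage statistics.
- **registration** — treat each ossicle as a rigid body and register small
  sub-volumes (SVs) chosen inside it from phase p₀ to every other phase pⱼ
  with intensity-based rigid registration (SimpleITK; Mattes mutual
  information or normalized cross-correlation, regular-step gradient
  descent, sub-voxel accurate), yielding per-SV transforms
  `xⱼ = Rⱼ x₀ + tⱼ` about the SV center.
- **kinematics** — re-express all SV transforms of an ossicle at a common
  origin O₀ via `t⁽⁰⁾ = t⁽ⁱ⁾ + (R − I)(O₀ − O⁽ⁱ⁾)`, discard outlier SVs
  (any parameter beyond 5× the median magnitude, then beyond 2σ of the
  survivor mean), average the seven motion parameters component-wise per
  phase, and derive the principal rotation axis over the cycle (axis-angle
  formalism throughout).
- **displacement** — carry anatomical ROI points (umbo, lenticular process,
  stapes footplate, …) through the mean transforms, sign the per-phase
  displacement norms by their projection on the dominant direction, and fit
  the constrained sine `D(t) = A·sin(2π(f·t + φ))` with *f* fixed at the
  stimulation frequency (closed-form least squares; reports A, φ, R², the
  peak-to-peak 2A, and amplitude ratios between stimulation levels).
  A confirmed-static region run through the same pipeline sets the noise
  floor below which amplitudes are flagged unreliable.
- **planar** — registration-free QC: intensity-profile-vs-phase matrices
  with sub-voxel extreme-shift estimation, and standard-deviation
  projections that highlight moving edges.
- **phantom** — synthetic 4D phantoms: 2–4 independently moving textured
  rigid bodies over a static background shell, sinusoidal rigid motion
  (rotations ≤ 2°, translations ≤ 3 voxels), 2.75 µm voxels, optional
  Gaussian noise, plus a simulated 2 kHz frame clock against a 128 Hz
  gating sine — with exact ground-truth transforms for every phase, so the
  whole pipeline is testable without any experimental data.
- **pipeline** — one-config orchestration of all stages, deterministic
  under a fixed seed.

## Worked example

```python
import numpy as np
import ossimotion as om

# a moving capsule ("ossicle") and a still ellipsoid ("temporal bone")
bodies = (
    om.BodySpec("mover", "capsule", (24, 32, 32), (8, 8, 14), texture_seed=21,
                motion_axis=(0, 1, 0), angle_amplitude_deg=1.0,
                translation_amplitude=(1.0, 0, 0.3)),
    om.BodySpec("still", "ellipsoid", (48, 32, 32), (10, 9, 9), texture_seed=42),
)
spec = om.PhantomSpec(grid_shape=(64, 64, 64), bodies=bodies,
                      noise_sigma=0.05, seed=11)          # SNR 20
cfg = om.RunConfig(
    phantom_spec=spec,
    subvolumes=(om.SubVolumeSpec("mover", (24, 32, 26), (9, 9, 7)),
                om.SubVolumeSpec("mover", (24, 32, 40), (9, 9, 7)),
                om.SubVolumeSpec("still", (48, 32, 28), (10, 9, 6)),
                om.SubVolumeSpec("still", (48, 32, 38), (10, 9, 5))),
    rois=(om.ROIPointSet("tip", "mover", np.array([[24.0, 32.0, 45.0]])),),
    static_labels=("still",),
    registration=om.RegistrationParams(metric="normalized_cross_correlation"),
    seed=11,
)
res = om.run_motion_extraction(cfg)
fit = res.fits["tip"]
nf = res.noise_reports["still"]
print(f"tip: A = {fit.A_um:.2f} um, phi = {fit.phi_cycles:.3f} cycles, R2 = {fit.R2:.4f}")
print(f"noise floor: {nf.max_point_displacement_um:.3f} um")
```

prints

```
tip: A = 3.48 um, phi = 0.501 cycles, R2 = 0.9997
noise floor: 0.134 um
```

The "tip" ROI sits 13 voxels from the rotation axis of a body rotating
±1° and translating ±1 voxel, so its fitted amplitude (3.5 µm ≈ 1.3 voxels)
combines the lever arm with the translation. φ is defined relative to the
sign-reference direction picked at the largest-displacement phase, so it
carries a half-cycle ambiguity: 0.501 ≈ 0.5 means the signed norm is in
antiphase with that (arbitrary) reference, i.e. the motion itself is in
phase with the gating sine. The 0.13 µm noise floor — the apparent motion
of the still body — is ~25× smaller than the measured amplitude.

A thin CLI wraps the common steps:

```
ossimotion phantom --out vols --grid 96 --seed 1
ossimotion gate --timing timing.csv --gating gating.yaml --n-phases 10 --out gated
ossimotion stdproj --phases vols --axis z --out std.tif
```

## Layout

```
src/ossimotion/   phantom, postgating, registration, kinematics,
                  displacement, planar, pipeline, geometry, series, io, cli
tests/            unit + property + acceptance tests (pytest, hypothesis)
docs/methods.md   models, conventions, parameter choices, limitations
```
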