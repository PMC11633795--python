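# Methods

This note documents the models, numerical procedures and design decisions
behind `dirqa`, in the spirit of a physics methods section: what is
computed, under which assumptions, and what passing tests do and do not
demonstrate.

## The QA model

The central idea is *simulate-then-measure*: because no real patient pair
comes with a known deformation, the toolkit manufactures one. A planning
image is deformed by a constructed displacement field `t` (the ground
truth); a candidate registration produces `u`; the QA quantities are
functions of `u − t` — directly (geometric error) or through the dose
distribution (dosimetric error). All displacement fields use the
**push-forward convention**: a material point at planning position `p` lies
at `p + u(p)` in the deformed anatomy. This convention is chosen because
every QA quantity is defined through point correspondence; resampling
(warping) uses the fixed-point inverse instead.

Axes are fixed package-wide as axis0 = LR, axis1 = AP, axis2 = SI, with
physical coordinates in mm from the lattice origin; displacement components
are stored in the same order. This removes any ambiguity in the per-axis
error decomposition.

## Ground-truth deformation

**Respiratory component.** Proprietary biomechanical lung models are not
reproducible, so the respiratory field is a separable parametric stand-in
that preserves the clinically relevant features: SI-dominant motion that
peaks at the diaphragm and is largest anteriorly,

    u_SI(y, z) = −A · exp(−(z − z_d)² / 2σ_z²) · w(y),

where `z_d` is the inferior extent of the lung mask, `σ_z` = 40 mm the
axial decay length, and `w(y)` a raised-cosine ramp from 1 anteriorly to 0
at the anterior edge of the spine over 80 mm (the spine and posterior
tissues stay put; vertebral motion during quiet breathing is negligible).
Amplitudes: presets low/medium/high = 10/20/38 mm peak SI displacement.
The analytic slope bounds `A·e^{−1/2}/σ_z` and `A·π/(2·80)` are checked
(< 1) before the field is built, and the discrete finite-difference
gradient is re-checked on the lattice: a slope below one guarantees the
map `p ↦ p + u(p)` is invertible, and makes the inversion iteration a
contraction. Amplitudes too large for the decay lengths raise an error
rather than producing a folding field.

**Digestive component.** A hard, uniform translation (default +5 mm AP and
+5 mm LR; signs configurable) applied to every voxel of a gastrointestinal
organ mask and exactly zero outside. The deliberate discontinuity at the
organ boundary mimics the independent sliding/peristaltic shift of GI
organs. The combined ground truth is the voxelwise vector sum. Because
correspondence-based QA uses the forward field only, the discontinuity is
never inverted where it matters; an optional boundary feather exists but is
off by default (the uniform shift is the modeled condition).

**Inversion and warping.** The inverse displacement solves
`v(p) = −u(p + v(p))` by fixed-point iteration (default 50 iterations,
0.01 mm tolerance). During iteration the field is sampled with
edge-replication beyond its lattice: boundary points whose preimage lies
outside the volume otherwise break the contraction. Residuals
`‖u(p+v(p)) + v(p)‖` are exposed via `composition_residual`; for the high
respiratory preset they are below 0.01 mm inside the eroded body. Warping
is trilinear for intensities and dose, nearest-neighbor for masks;
out-of-field samples are filled with −1000 HU (intensity) or 0 (mask/dose).

## Phantom and dose model

The phantom is stylized (ellipsoids and tubes) by design: every QA quantity
depends only on masks, intensities and geometry. Shapes are parameterized
as fractions of the physical extent, so any grid ≥ 32³ is valid; the
default study grid is 96³ at 2 mm. Tissue values: soft ~40 HU, lung
−700 HU, spine 700 HU, with small organ-specific offsets. Two stochastic
components are added from the run seed: a smooth intra-body texture
(σ = 60 HU, 8 mm correlation length) — real soft tissue is heterogeneous,
and an intensity-based DIR needs that heterogeneity to be identifiable away
from organ boundaries — and white noise (σ = 20 HU). The deformed CT is
produced by warping the planning CT, so its noise deforms with the anatomy,
exactly as a synthetically deformed scan behaves.

The dose distribution is a **static analytic cloud**: Gaussian boost
kernels centered on the GTV centroid (one per prescription level, peak
increments equal to the level increments, scales shrinking inward — a
dose-painting pattern) plus a wide low-dose bath (10% of the highest
level). Because the cloud is a function of room coordinates only, sampling
it at truth- and candidate-corresponded points isolates precisely the
DIR-induced dose error; there are no density or heterogeneity effects, and
that is a documented limitation, not an approximation error. The highest
prescription level is the normalization reference for all percentage
metrics.

## Candidate registration

The built-in candidate is a multi-resolution symmetric-forces demons
(SimpleITK filter inside a hand-built 3-level pyramid; 100/60/30 iterations;
update and field smoothing of 1.0 and 1.5 voxels), preceded by a
translation-only rigid pre-alignment maximizing normalized
cross-correlation over the dilated spine mask (exhaustive ±12 mm
integer-voxel search, per-axis parabolic refinement; refinement is skipped
when the integer peak is an exact match, where it would only add bias).
Rotation is omitted deliberately: same-patient spine alignment is
translation-dominated, and the exhaustive search stays exact and testable.
Demons natively estimates the resampling (pull-back) field; the rigid
translation is composed exactly at that level (`d_total = d + t`) before a
single inversion to push-forward. The demons is a reproducible stand-in
for commercial engines, not an emulation of their error patterns; external
DVFs are first-class inputs via `import_dvf`, which refuses to guess an
undeclared convention.

## Analysis choices

* **Analysis grid**: 1 mm isotropic, origin aligned to the reference
  lattice, bounding box the intersection of the two fields' extents snapped
  outward to whole mm; voxels outside either source extent are flagged and
  excluded from statistics rather than filled. Vector components are
  resampled trilinearly and never re-oriented.
* **ROI statistics**: computed over planning-space ROIs transferred to the
  analysis grid by nearest-neighbor; "entire body" statistics mean all
  voxels inside the body mask. Percentiles use linear interpolation between
  order statistics throughout.
* **Dose error sign**: truth-side minus candidate-side, kept signed
  everywhere; the panel's "maximum" is the signed value of largest
  magnitude. "Top 1 cc" is the mean signed error over the ⌈1 cm³ / voxel
  volume⌉ ROI voxels of largest absolute error (whole ROI, with a warning,
  if the ROI is smaller). Dmax/Dmin errors are DVH-metric-level differences,
  distinct from the voxelwise extremum. Deformed-side DVH metrics are
  computed on both the truth- and the candidate-corresponded dose; the
  truth-corresponded side is the reference.
* **Binned correlation**: equal-width bins over the observed key range,
  default 75 (within the customary 50–100), per-bin mean and 25th–75th
  percentile range, bins with fewer than 10 voxels excluded from
  correlation. The coefficient is Pearson's r on the binned summaries — a
  linear coefficient matches how such analyses are thresholded in practice.
  Zero-variance axes are reported as flagged degenerate results (rendered
  as nulls), never as numbers.

## Problem sizes and determinism

The default study conditions are a 96³ × 2 mm phantom (≈7.1M analysis-grid
voxels after 1 mm resampling), high respiratory preset, 5 mm digestive
shifts, and a 4500/7500 cGy two-level prescription. Unit tests use coarser
grids (48³ × 3 mm) where the property under test is grid-independent. All
randomness (phantom texture and noise) flows from a single integer seed;
demons and every analysis step are deterministic, so a fixed seed yields a
byte-identical QA record.

## Limitations

* Anatomy and dose are stylized; passing tests demonstrate correctness of
  the QA mathematics and the achievable accuracy of the demons stand-in on
  this phantom — not the clinical error pattern of any commercial DIR on
  patient CTs.
* The dose cloud ignores tissue density, so "recalculation on the deformed
  CT" is exact by construction; real recalculation adds heterogeneity
  effects the QA would fold into its error estimate.
* The respiratory model is separable and time-free (no 4-D trajectories,
  no sliding interfaces); digestive motion is rigid translation only.
* Multi-modality (e.g. CBCT-to-CT) registration QA is out of scope; error
  patterns there differ.
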