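# dirqa — patient-specific QA for deformable image registration

`dirqa` is a toolkit for **patient-specific quality assurance of deformable
image registration (DIR)** in abdominal radiotherapy. DIR underpins contour
propagation, adaptive replanning and dose accumulation, yet its per-patient
accuracy is rarely verified: commercial algorithms disagree with each other,
and the geometric error they commit turns directly into dose-accumulation
error near steep dose gradients. `dirqa` quantifies both, against a **known
ground truth** that it constructs itself.

It is aimed at medical physicists and registration researchers who want a
reproducible, scriptable QA record for a DIR algorithm — whether that
algorithm is the built-in demons registration or a displacement field
exported from a commercial system.

## What it computes

**Ground truth.** A synthetic abdominal phantom (body, lungs, spine, GTV
near the spine, stomach+duodenum, small bowel) is deformed by a known
displacement vector field (DVF): a smooth respiratory field, SI-dominant
and peaking at the diaphragm, with selectable amplitude (low/medium/high =
10/20/38 mm), plus rigid 5 mm anterior–posterior and lateral "digestive"
shifts applied uniformly inside the gastrointestinal organ masks. Warping
the planning CT with this field yields a ground-truth deformed CT; the pair
is the test input for any DIR.

**Geometric error.** Candidate and ground-truth DVFs are linearly resampled
to a 1 mm isotropic, origin-aligned analysis grid, and compared voxelwise:

```
magnitude error = sqrt( (u_AP − t_AP)² + (u_LR − t_LR)² + (u_SI − t_SI)² )
```

with `u` the candidate and `t` the ground-truth displacement (mm). Mean,
90th-percentile, maximum and histograms are reported per ROI (GTV,
stomach+duodenum, small bowel, entire body).

**Dosimetric error.** An analytic multi-level dose cloud `D(p)` (dose
painting, e.g. 4500/7500 cGy) stands in for the recalculated plan. For every
planning voxel A the two correspondences A′ = A + t(A) and A″ = A + u(A)
are evaluated, and the signed dose error is `e(A) = D(A′) − D(A″)` in cGy.
Per ROI, six metrics are reported as percentages of the highest prescription
level: Dmax error, Dmin error, mean and maximum (largest-magnitude signed)
voxel dose error, its 95th percentile, and the mean error over the worst
1 cm³. DVH metrics (Dmax, Dmin, mean, D95%, V100%) are computed on both the
truth- and candidate-corresponded dose.

**Correlation.** Voxels are grouped into 50–100 equal-width bins by
ground-truth displacement magnitude or by DIR magnitude error; per bin, the
mean and the 25th–75th-percentile range of the tracked statistic are
computed, and Pearson coefficients relate bin centers to those summaries —
showing how registration error, and the dose error it induces, scale with
motion magnitude.

## Worked example

```python
from dirqa import run_workflow

report = run_workflow({
    "seed": 7,
    "phantom": {"shape": [64, 64, 64], "spacing": [3.0, 3.0, 3.0]},
    "deformation": {"preset": "high"},          # 38 mm respiratory peak
    "candidate": {"source": "demons"},          # built-in candidate DIR
    "prescription": {"levels": [4500.0, 7500.0]},
})

for roi, s in report.error_summary.items():
    print(f"{roi:16s} mean={s.mean:5.2f} mm   p90={s.p90:5.2f} mm")
p = report.dose_panels["gtv"]
print(f"GTV dose errors (% of 7500 cGy): mean={p.mean_error_pct:+.2f} "
      f"max={p.max_error_pct:+.2f} p95={p.p95_error_pct:+.2f}")
```

prints

```
body             mean= 0.97 mm   p90= 3.09 mm
gtv              mean= 0.39 mm   p90= 0.53 mm
stomach_duodenum mean= 5.53 mm   p90= 7.33 mm
small_bowel      mean= 2.93 mm   p90= 4.55 mm
GTV dose errors (% of 7500 cGy): mean=+0.30 max=+0.99 p95=+0.93
```

Reading: the demons candidate tracks the smooth respiratory motion well
(sub-millimetre mean error in the GTV) but, like any intensity-based DIR,
struggles with the discontinuous digestive shifts — the stomach+duodenum
mean error of ~5.5 mm is close to the √(5²+5²) ≈ 7.1 mm shift it failed to
see inside a near-uniform organ. Because the GTV sits in a flat region of
the dose cloud, its residual geometric error converts into well under 1% of
the prescription.

The same pipeline runs from the shell:

```bash
dirqa run-all --config config.yaml --seed 7 --out qa_record/
dirqa simulate --seed 7 --out sim/          # phantom + ground truth only
dirqa register --fixed sim/deformed_ct.nii.gz --moving sim/planning_ct.nii.gz \
               --spine sim/structures/spine.nii.gz --out dvf.nii.gz
dirqa qa-geom  --truth sim/gt_dvf.nii.gz --cand dvf.nii.gz \
               --structs sim/structures --out geom.json
```

External DVFs are imported with `dirqa import-dvf`; a JSON sidecar (or the
`--convention` flag) must declare whether the field is push-forward or
pull-back — pull-back fields are inverted on import.

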