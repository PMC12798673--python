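# pelviflow

Frame-by-frame motion tracking and kinematic analysis of vaginal pessaries
and pelvic floor structures on dynamic midsagittal MRI.

## The problem

Vaginal pessaries are the first-line nonsurgical treatment for pelvic organ
prolapse, yet how they interact mechanically with the pelvic floor is
poorly understood: conventional dynamic-MRI analyses compare only a resting
frame against a maximal-Valsalva frame and discard everything in between.
`pelviflow` is a pipeline for quantifying that interaction continuously.
Given a dynamic 2D+time midsagittal sequence and a one-time manual
selection of six regions of interest — the distal and proximal pessary rim
cross-sections, the perineal body, the anorectal angle, and two bony
reference landmarks (inferior pubic point, sacrococcygeal joint) — it:

1. **tracks** every ROI through the sequence with a pyramidal Lucas–Kanade
   optical-flow tracker (Gauss–Newton on the windowed SSD objective, with
   forward–backward consistency gating);
2. **normalizes** the tracked coordinates, per frame, into the 2D
   midsagittal restriction of the Pelvic Inclination Correction System
   (PICS): origin at the inferior pubic point, x-axis along the
   pubis→sacrococcygeal (SCIPP) line rotated by the standard 34°
   inclination offset, +x posterior, +y caudal — so global changes of
   patient posture cancel and subjects become comparable;
3. **derives** per-frame kinematics: urogenital hiatus size (pubic point ↔
   perineal body distance), levator hiatus size (pubic point ↔ anorectal
   angle), pessary displacement from rest (components + magnitude), and
   pessary axis orientation;
4. **correlates** distal-rim displacement with hiatus enlargement, both
   frame-by-frame (all valid frames pooled) and start-to-end (one point per
   subject), reporting Pearson *r* with Fisher-z 95% CIs
   (`tanh(atanh r ± z/√(n−3))`) and two-sided p-values from
   `t = r·√((n−2)/(1−r²))`; tracking reproducibility is quantified with
   ICC(2,1).

No patient imaging is distributed. A synthetic phantom generator renders
supine-Valsalva look-alike sequences with exact ground-truth trajectories
(soft structures descend with a configurable displacement–hiatus coupling;
bony landmarks move only rigidly), so the whole pipeline is testable and
its accuracy measurable.

## Worked example

Run the full pipeline on six synthetic subjects (descent amplitudes
5–20 mm) and print the pooled statistics:

```python
from pelviflow import RunConfig, run_pipeline

stats = run_pipeline(RunConfig(out_dir="demo_run", phantom_subjects=6, seed=1))
for a in stats["analyses"]:
    print(f"{a['mode']:>10} {a['y_var']}: r = {a['r']:.2f} "
          f"[{a['ci_low']:.2f}, {a['ci_high']:.2f}], p = {a['p']:.3g} (n = {a['n']})")
```

```
 framewise ugh_change_mm: r = 1.00 [1.00, 1.00], p = 0 (n = 174)
 start_end ugh_change_mm: r = 1.00 [1.00, 1.00], p = 6.21e-09 (n = 6)
 framewise lh_change_mm: r = 1.00 [1.00, 1.00], p = 0 (n = 174)
 start_end lh_change_mm: r = 1.00 [1.00, 1.00], p = 6.67e-08 (n = 6)
```

The correlations are ~1 because the default phantoms share one
deterministic coupling (0.9 mm hiatus enlargement per mm of distal-rim
descent) and tracking error is far below the signal — i.e. the pipeline
recovers the generator's construction. With realistic between-subject
heterogeneity (per-subject couplings, frame noise, subject-level endpoint
noise) the two analysis modes separate:

```python
from pelviflow import make_kinematics_ensemble, framewise_correlation, start_end_correlation

tabs, _ = make_kinematics_ensemble(6, 30, noise_sd=1.0, per_subject_coupling_sd=0.25,
                                   endpoint_noise_sd=3.0, seed=1)
print(framewise_correlation(tabs))   # r = 0.93 [0.91, 0.95], p ≈ 0,     n = 174
print(start_end_correlation(tabs))   # r = 0.71 [-0.23, 0.97], p = 0.112, n = 6
```

The frame-by-frame analysis extracts a strong, significant association from
the same data in which the six-point start-to-end comparison cannot reach
significance — the methodological point the pipeline exists to make.

Per-subject outputs land in the run directory: `tracks.csv` (pixel anchors
with residuals, forward–backward errors and validity flags),
`pics_tracks.csv` (PICS mm), `kinematics.csv`, plus `stats.json`,
trajectory/scatter figures and a run log. The same stages are available
from the shell:

```bash
pelviflow simulate --seed 3 --out phantom/
pelviflow track --sequence phantom/sequence.nii.gz --rois phantom/rois.json --out tracks.csv
pelviflow analyze --kinematics runs/ --out stats.json
pelviflow report --stats stats.json
```

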