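# Methods

## Tracking model

Each region of interest is tracked as a rigidly translating intensity
window. For frames *I* (at *t*) and *J* (at *t*+1) and a window *W*
centred on the structure, the displacement **d** minimizes

    E(d) = Σ_{p∈W} ( I(p) − J(p + d) )².

The minimizer is found by Gauss–Newton iteration: with spatial gradients
(I_x, I_y) of the Gaussian-smoothed (σ = 1 px, central differences) frame,
accumulate the gradient normal matrix G = Σ[I_x², I_xI_y; I_xI_y, I_y²]
and mismatch vector b = Σ δI·(I_x, I_y), update d ← d + G⁻¹b, and stop
when ‖update‖ < `eps_px`. Sub-pixel samples of *J* use edge-clamped
bilinear interpolation. This is the classical iterative Lucas–Kanade
scheme; a coarse-to-fine pyramid (anti-alias Gaussian smoothing, σ =
downscale/2, then decimation) extends the capture range beyond the window
radius, the running displacement being rescaled by the downscale factor
between levels.

Assumptions: local motion is a pure translation over one frame interval
(rotation/deformation within a window is treated as noise), intensity is
approximately conserved between frames, and the window contains texture
(the smaller eigenvalue of G per pixel must exceed `min_texture`,
evaluated on [0, 1]-normalized intensities; below it the step is declared
singular rather than inverted).

Positions are chained frame-to-frame from the frame-0 anchor rather than
re-registered to the initial template: a Valsalva deforms appearance
monotonically, so chaining stays locked on the evolving appearance while a
fixed template would fail late in the maneuver. The cost of chaining is
drift, which is surfaced, not hidden: after every forward step a backward
step is computed and the forward–backward error ‖d_fwd + d_bwd‖ recorded;
rows exceeding `fb_max_px` (or failing convergence, or leaving the frame)
are flagged invalid but never silently dropped, and chaining continues
from the forward estimate so later recovery remains possible.

Reported coordinates are the upper-left corner of the ROI window, the
convention of the coordinate tables throughout the package.

### Tracker parameters

| parameter | default | meaning |
|---|---|---|
| `window_half_px` | 10 | 21×21 px tracking window |
| `pyramid_levels` / `downscale` | 3 / 2 | capture range ≈ 40 px |
| `max_iter` / `eps_px` | 30 / 0.01 px | Gauss–Newton stopping rule |
| `fb_max_px` | 1.0 px | forward–backward validity gate |
| `min_texture` | 1e-6 | per-pixel min eigenvalue of G, normalized units |
| `grad_sigma` | 1 px | smoothing for gradient estimation |

These are conventional Lucas–Kanade settings, all config-exposed; none are
claimed to equal any particular prior implementation's constants.

## Coordinate normalization (PICS, 2D restriction)

The Pelvic Inclination Correction System anchors a body-fixed frame on the
SCIPP line (inferior pubic point → sacrococcygeal joint). Restricted to
the midsagittal plane this is an in-plane rotation plus translation, so
with exactly two landmarks the transform is constructed analytically —
origin at the pubic point, x-axis the SCIPP unit vector rotated by the
inclination offset (default 34°, the published convention; configurable
because "modified" variants exist), y perpendicular — rather than fitted.
Sign conventions: +x posterior, +y caudal, so descent and hiatus
enlargement are both positive-going. Flipping exactly one axis sign would
produce a reflection and is rejected; the transform is always a proper
rotation.

The transform is re-fitted on every frame from that frame's tracked
landmarks. Because a global rigid motion of the scene moves the landmarks
identically, it cancels exactly in PICS coordinates — this is the formal
sense in which the normalization "adjusts for changes in pelvic
inclination". Frames with invalid or degenerate (< 1 mm apart) landmarks
yield flagged rows; nothing is interpolated.

Pixel anchors are scaled to mm per axis by the pixel spacing before the
transform; the tracker itself runs in pixel space, so anisotropic spacing
is handled without resampling.

## Kinematics

Urogenital hiatus size = ‖pubic point − perineal body‖; levator hiatus
size = ‖pubic point − anorectal angle‖ (mm, per frame — Euclidean
distances, hence independent of the PICS rotation). Displacement of each
rim is measured from the frame-0 rest position in PICS mm; the +y
component is caudal descent. The pessary axis angle is the orientation of
the distal→proximal rim vector versus the PICS x-axis, in (−180°, 180°],
undefined (flagged) when the rims are within 1 mm. A frame's kinematics
row is valid only when every constituent track is valid.

Distances use the upper-left window anchors. With uniform window sizes the
anchor offsets cancel exactly in every distance and in the PICS fit; with
mixed window sizes a small bias of order ‖offset difference‖ × inclination
change would enter — a limitation of the corner convention on real data,
where window-centroid mode (non-default) can be used instead.

## Correlation statistics

Pearson r with Fisher-z 95% CI, tanh(atanh r ± z_{0.975}/√(n−3)), and
two-sided p from t = r√((n−2)/(1−r²)) on n−2 df. |r| = 1 returns p = 0
and the degenerate CI [r, r]. Two analysis modes:

- **framewise**: all valid (subject, frame) pairs pooled; default x =
  distal-rim displacement magnitude, y = hiatus change from rest (removing
  between-subject size offsets; raw-size mode available). The rest frame —
  the displacement reference, identically (0, 0) — is excluded from the
  pool; it carries no information, and its exclusion makes a two-frame
  sequence degenerate exactly to the start–end analysis. The CI treats
  pooled frames as independent, which is optimistic for clustered
  within-subject data; a subject-level cluster bootstrap is provided as a
  diagnostic beyond that convention.
- **start_end**: one (Δdisplacement, Δhiatus) point per subject between
  first and last valid frames; requires ≥ 4 subjects.

Reproducibility uses ICC(2,1), two-way random effects, absolute agreement,
single measurement, computed from the ANOVA decomposition
(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n); incomplete matrices are
rejected, never imputed.

## Synthetic phantom

The generator emulates a supine Valsalva in a 256×256 px, 1 mm/px,
30-frame midsagittal scene. A monotone strain profile s(t) (default
smoothstep, s(0)=0, s(end)=1) drives:

- distal rim: caudal descent D·s(t), default D = 15 mm;
- perineal body / anorectal angle: radial motion away from the pubic point
  such that hiatus enlargement is exactly κ·D·s(t) (defaults κ_UGH = 0.9,
  κ_LH = 0.7);
- proximal rim: rides with the distal rim while the rim axis rotates by a
  prescribed angle (default 10°); rim separation 70 mm, the midsagittal
  cross-section spacing of a size-3/4 ring pessary;
- the whole scene: a global rigid motion (rotation, default 10°, about the
  scene centre plus optional drift), applied last — exactly the outer
  motion the per-frame PICS refit must undo. Bony landmarks move only by
  this global motion.

Rendering composites a fixed seeded texture patch per structure
(high-contrast for bone so landmark tracking is never the limiting error;
hypointense discs on brighter tissue for the rims, echoing their MRI
appearance) onto a static low-frequency background with sub-pixel bilinear
shifts, then adds Gaussian intensity noise (default σ = 0.01 of the
dynamic range; Gaussian rather than Rician because at these levels the
distinction is immaterial to what is being tested). Because each patch
translates rigidly with its structure, the local image motion equals the
ground-truth trajectory and tracking error is well defined. All
randomness derives from one seed; output is bit-reproducible.

Two numerical details keep the emitted truth exact: the rest layout is
snapped to integer pixels *before* trajectories are derived (so ROI
anchors equal frame-0 truth exactly while the couplings remain exact
closed forms), and truth positions are defined as the structure-centre
trajectory minus the fixed half-window offset — the quantity a
translation-only tracker can actually report under scene rotation.

What the phantom does **not** emulate: tissue deformation within a
structure, appearance change, through-plane motion, MRI physics
(bias fields, ghosting, Rician magnitude noise at low SNR), or anatomic
variability of the structure layout. Passing the recovery tests therefore
demonstrates correctness of the tracking/normalization/statistics
machinery under translation-dominated motion — not clinical-grade accuracy
on patient imaging, where appearance change and deformation would stress
the forward–backward gate much harder.

The kinematics-only ensemble generator produces correlation test
substrates without imaging: per subject, displacement = random amplitude
(5–20 mm) × s(t); hiatus change = coupling_i × displacement +
subject-level endpoint offset × s(t) + iid frame noise. When a target
pooled correlation is requested, the frame-noise sd is solved from the
realized design moments (the drawn amplitudes and couplings), so that
conditional on the design the pooled correlation equals the target —
which also makes the Fisher-z interval's nominal coverage apply. An
unattainable target (heterogeneity alone depressing the correlation below
it) raises an error rather than silently clipping.

## Problem sizes used in validation

The shipped validation runs use 10–30 frame sequences at 256×256 px, six
to ten synthetic subjects per analysis, three jittered repetitions for the
ICC protocol, and 100-seed Monte-Carlo loops for the statistical
properties — sizes at which every quantity under test (sub-pixel accuracy,
coupling recovery, interval coverage, analysis-mode ordering) is already
well resolved.

## Known limitations

- Frame-to-frame chaining accumulates drift on long sequences; the
  forward–backward gate flags but does not correct it.
- The pooled framewise CI understates uncertainty under strong
  within-subject correlation; the cluster bootstrap is the honest
  companion number.
- The 2D PICS restriction ignores out-of-plane inclination change.
- Start–end analyses on few subjects are fragile by construction; that
  fragility is precisely what the framewise mode demonstrates against.
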