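# Methods

This note documents the models, parameter choices, and numerical decisions
behind `vertelab`, and what the synthetic-phantom evaluation does and does
not demonstrate.

## Coordinate conventions

All world coordinates are millimetres in RAS orientation (x right,
y anterior, z superior); volumes read from NIfTI are reoriented to the
closest canonical axes. "Rostral" is +z; centerlines and profiles are
ordered rostral → caudal with arc length starting at 0 at the most rostral
point. Vertebral levels are numeric: 1–7 cervical, 8–19 thoracic, 20–24
lumbar; a disk is keyed by its upper vertebra (disk 2 = C2–C3).

## Spine profile

The cord centerline (per-slice mask centroids, smoothed over 5 mm and
resampled to 1 mm arc steps — without smoothing, sub-voxel centroid jitter
inflates the cumulative arc length by more than 1 mm over a whole-spine
field of view) is translated 15 mm along +y so it runs through the
vertebral column. The 15 mm shift, the 10 mm × 10 mm patch, and the 1 mm
step are the method's standard operating values and are configurable. The
patch at each sample is spanned by the anatomical left–right axis and the
tangent-orthogonal component of anterior–posterior; patch values are
trilinearly interpolated, and points outside the field of view are excluded
from the average rather than zero-filled (a sample whose entire patch is
outside is filled from its neighbours; more than 20 % such samples is an
error).

### Detrending

The baseline model is `a + b·s + c·sin(2πs/λ + φ)`. Jointly fitting λ with
the linear part is degenerate — a sinusoid with a period much longer than
the profile is indistinguishable from a line, and the joint fit diverges —
so λ is selected on an 8-point geometric grid between 120 mm (several times
the largest inter-disk gap, so the sinusoid cannot absorb disk peaks) and
4× the profile span, fitting the remaining linear coefficients robustly
(soft-L1 loss, scale = 1.4826·MAD) for each candidate and keeping the
lowest-cost fit. A second, local baseline term — the running median of the
residual over a 45 mm window — removes deviations broader than a few disk
widths that no low-order global model can follow, most importantly the deep
plateau left by a signal-dropout artifact spanning several vertebral
levels. Disk peaks (≈ 8 mm support, ≥ 16 mm spacing) occupy well under half
of any window, so the running median tracks the inter-peak baseline and
peak heights survive within a few percent. The running median necessarily
leaves edge residuals at a sharp artifact boundary (a 90 % dropout step
cannot be removed by any baseline model); the detection stage bounds their
influence (see below).

### Contrast normalization

T2-like profiles are divided by their maximum. T1-like profiles are divided
by their most negative value, which simultaneously rescales by the deepest
trough and flips the sign, so both contrasts present unit-height positive
peaks to a single downstream detector. Whether a T1 profile still needs the
flip is decided by comparing the energy of its negative vs positive
excursions: the disk train dominates whichever side it is on, whereas a
single narrow artifact spike — which can exceed the disk amplitude — does
not. This makes normalization idempotent and robust to dropout-slab edge
residuals.

## Disk pattern and correlation score

The pattern is `sinc(x/width)^(2n)` (normalized sinc) sampled at 11 points
spaced at the profile step, width 15 mm (FWHM ≈ disk width), n = 10;
labeling accuracy is unchanged for width ∈ [10, 20] mm and n ∈ [8, 12],
which the test suite checks.

The correlation score at an offset is the least-squares amplitude of the
mean-centered pattern within the mean-centered 11-sample window,
`⟨w_c, p_c⟩ / ⟨p_c, p_c⟩`. Two properties motivate this over a fully
normalized correlation coefficient:

- after profile and peak normalization a clean disk scores ≈ 1 regardless
  of the acquisition's intensity scale, so scores are comparable across
  subjects and contrasts, and
- the score is proportional to the *remaining amplitude* of a peak, so a
  disk attenuated by an artifact scores low even when its residual bump is
  noise-free — which is precisely the situation the 40 %-of-median fallback
  rule must detect. A correlation coefficient is amplitude-invariant and
  would score such a disk as highly as a healthy one.

Accepted-peak positions are refined to sub-sample precision by parabolic
interpolation of the correlation peak (clamped to the search window).

## First-disk detection

The C2–C3 disk is the most rostral local maximum of the correlation curve
that passes a noise gate: score ≥ 0.5 (absolute floor) and ≥ half the
global correlation maximum, the latter capped at 1 (the nominal clean-disk
score) so a super-unity artifact response further down the spine cannot
gate out the true first disk. Candidates must additionally match the
pattern in shape (window-vs-pattern correlation coefficient ≥ 0.9): on an
amplitude-normalized profile with no disks at all, the largest noise
excursion is unit-height by construction and only its shape betrays it.
Phantom disks score 0.97–1.0 on this measure across the tested pattern
widths. If no candidate qualifies, the caller is instructed to supply a
starting level — the path also used when C2 is outside the field of view
(the user names the first visible vertebra; its disk is still located
automatically as the most rostral qualifying peak).

## Peak normalization

A cubic spline is interpolated through the profile's rough local maxima
(prominence ≥ 10 % of the profile maximum, minimum separation half the
smallest template gap, height ≥ 20 % of the maximum) and divided out; the
envelope is held constant beyond the outermost maxima and floored at 20 %
of the profile maximum. The height gate keeps artifact-destroyed disks
(residual bumps ≈ 10 % after a 90 % dropout) from being re-inflated into
detectable peaks, which would silently defeat the fallback mechanism; with
fewer than three usable maxima the transform is the identity and a warning
is emitted.

## Sequential scan, ratio, and fallback

Scanning proceeds caudally from the first disk: predict the next disk at
the last accepted position plus `generic_distance(i) · ratio(i)`, refine
within ± 20 % of that gap, accept or fall back, update the ratio. Details:

- **Ratio.** `ratio = detected span ÷ template span`, measured from the
  first disk to the most recent *correlation-confirmed* disk and clamped to
  [0.7, 1.3]. Fallback detections sit exactly where the current ratio
  predicted them and therefore carry no scale information; including them
  would freeze an early error in place. The ratio engages only once the
  span covers at least two gaps: a single inter-disk distance has a few
  percent measurement noise, and rescaling the whole template by it shifts
  every subsequent ± 20 % search window enough to capture artifact-edge
  structure one level early. With the two-gap requirement a uniform 15 %
  anatomical rescaling is still locked onto within the first three disks
  (the search window retains ≈ 1 mm of margin at each pre-lock step), which
  the scale-equivariance test exercises.
- **Fallback.** A refinement is rejected when its score is below 40 % of
  the median of previously accepted scores (the first disk's score included;
  an empty history always accepts). The fallback places the disk at its
  predicted location. Artifact-edge residuals can still win a *correlated*
  acceptance near a slab boundary, but the search window bounds the
  resulting position error to ± 20 % of one gap — small enough that the
  disk remains nearest its own reference position and no level is
  mislabeled.
- **Termination.** The scan stops when the template is exhausted, when the
  prediction passes the caudal end of the profile, or after two consecutive
  fallbacks whose search windows were clipped by the caudal end (those
  unconfirmable detections are removed).

## Projection, labeling, evaluation

Detected disks (3-D points on the shifted curve) are projected to the
nearest point of the centerline polyline; an ordering inversion is an
error. Samples strictly caudal to the disk between vertebrae n and n+1 are
labeled n+1 up to the next disk; the stretches rostral of the first and
caudal of the last disk receive the adjacent vertebra's index. A cord mask
is labeled by nearest centerline sample.

Evaluation is the published protocol at phantom scale: per-volume accuracy
is 100 only if every reference disk is detected and lies nearest its own
reference position (all-or-nothing), and the absolute position error is
aggregated across levels and volumes.

## The phantom

The phantom renders a vertebral column as a 10 mm-radius tube whose axial
intensity is a constant body level carrying raised-cosine disk bumps
(FWHM 4 mm), a 3.5 mm-radius cord 15 mm posterior to it, and a darker
background, on a 1 mm isotropic grid (64 × 96 × 368 mm). Both curves bend
sinusoidally in the anteroposterior and mediolateral directions
(amplitude 5 mm, period ≈ 300 mm), so profile sampling is genuinely 3-D.
The default disk layout runs C2–C3 through T8–T9 with gaps growing from
16 mm by 1 mm per level — the caudally increasing spacing that the distance
template encodes. Degradations: a multiplicative quadratic bias field along
z (± 20 %), additive Gaussian noise (SD 10 against a body level of 100,
SNR 10), and an optional multiplicative dropout slab spanning named
vertebral levels including their bounding disks (attenuation 0.9 emulates a
metallic implant). The disk/body contrast is specified as a CNR
(default 3) and converted to absolute contrast via the noise SD (reference
SD 10 for noiseless phantoms). Identical configurations and seeds give
bit-identical volumes.

Ground-truth disk positions on the cord are defined by orthogonal
projection of each disk's column-axis point onto the cord curve — the cord
point *adjacent* to the disk, which is what a human rater marks on the
cord. Under curvature this differs by up to ~2 mm from the equal-arc-length
point, and the pipeline's own output is defined by the same projection, so
the evaluation measures detection error rather than a parameterization
mismatch. Distances *between* disks (used when building templates from
labeled cohorts) are measured along the spine profile, where the phantom's
generator gaps are recovered to well under 0.5 mm.

What the phantom does **not** emulate: MR acquisition physics (no k-space,
Rician noise, or partial-volume modeling), surrounding soft-tissue anatomy,
vertebral shape variation, scoliosis-grade curvature, and inter-rater
labeling variability. Passing the phantom evaluation therefore demonstrates
the algorithm's mechanics — contrast handling, template rescaling, artifact
fallback — but the published error levels against human raters (≈ 2 mm)
include rater disagreement that synthetic ground truth does not reproduce;
phantom position errors are correspondingly smaller (≈ 0.25 mm mean).

## Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| shift_mm | 15 | anterior shift from cord to column |
| patch_lr_mm / patch_ap_mm | 10 / 10 | profile averaging patch extents |
| step_mm | 1 | profile arc-length step |
| pattern width / n | 15 mm / 10 | sinc FWHM and half-exponent |
| search_fraction | 0.2 | refinement half-width ÷ predicted gap |
| fallback_fraction | 0.4 | fallback threshold ÷ history median |
| ratio clamp | [0.7, 1.3] | bounds on the morphology scale factor |
| min_period_mm | 120 | lower bound on the detrend sinusoid period |
| local_window_mm | 45 | running-median baseline window |

## Known limitations

- The centerline extractor is a per-slice centroid tracker intended for
  phantom masks and clean cord segmentations; clinical use should supply a
  centerline from a dedicated propagation method.
- The first-disk shape gate (0.9) is deliberately tight; profiles whose
  most rostral disk is badly distorted should use the named-start path.
- The 15 mm anterior shift is fixed rather than scaled to subject size.
- Axial slices are treated as orthogonal to the column for rendering and
  slab placement; at the phantom's ≤ 6° tangent tilt the approximation is
  sub-percent.
- Vertebral vs spinal (neurological) level mismatch is out of scope; labels
  are vertebral.
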