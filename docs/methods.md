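# Methods

This note records the models, parameters and design choices behind the
package, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Problem setting

Thyroid eye disease (TED) presents with eyelid retraction, restricted eye
movements and periocular inflammation. All three can be assessed from
standardized frontal photographs: eyelid position is measured against the
pupil center and the corneal limbus, motility from the iris position in
extreme gaze, and inflammation from the appearance of the eyelids,
conjunctiva and the caruncle/plica complex (LCP). The package implements
the full measurement chain — calibration, segmentation, landmark
extraction, rule-based quantification, structure cropping and multi-label
inflammation classification — together with a synthetic image generator
that makes every stage testable without clinical data.

## Coordinate and unit conventions

Coordinates are 0-based `(row, col)` with rows increasing downward;
vertical distances are row differences and horizontal distances are column
differences. Physical lengths are millimetres; the bridge is a
`Calibration` derived from a rendered ruler of alternating 5 mm
black/white divisions: `mm_per_px = 5 / division_px`, with the division
length estimated as the median run length of the binarized strip profile
(end runs are discarded as truncated). The measured distance between the
punctum reference and the medial canthus is horizontal-only (column
difference), a choice the calibration test suite pins down; Euclidean
distance differs only by the canthal-line tilt, which the acquisition
geometry keeps near zero.

## Synthetic eye model

The generator is a parametric forward model of the acquisition setup, not
a photorealistic renderer.

* **Aperture.** Two parabolic eyelid arcs meet at the canthi; each apex
  sits on the pupil column. The half palpebral-fissure width is
  `lid_curvature x iris_radius` (default 2.4, about 14 mm).
* **Anatomy defaults** (millimetres): iris radius 5.8, pupil radius 1.8,
  upper apex (D_up) 4.3, lower apex (D_down) 5.6, LCP wedge width 3.0.
  Both lids overlap their limbus and the lower-minus-upper margin
  difference is 1.3 mm, so the default eye is comfortably normal under
  every rule.
* **Cohort sampling** jitters the anatomy within normal ranges chosen so
  that a healthy draw can never sit closer than about 0.3 mm / 5 px to a
  diagnostic threshold: iris 5.7–5.9 mm, upper apex 4.0–4.15 mm, lower
  apex = upper + 1.4–1.6 mm capped at iris − 0.15 mm, pupil radius
  2.2–2.6 mm (an indoor-photograph pupil; with the lids held fixed across
  gaze frames, a smaller pupil could disappear entirely behind the upper
  lid in full up-gaze, which would make the gaze-frame annotation
  impossible — the generator raises a structured error if any structure
  class is fully occluded).
* **Retraction** re-positions the affected arc so its margin sits the
  requested number of millimetres beyond the limbus; the truth fields
  (D_up, D_down, scleral show, category) are computed analytically from
  the arcs and disc positions, never from the raster.
* **Gaze frames** translate the iris/pupil discs and leave the lids fixed
  (the head and, to first order, the lids are constrained by the
  acquisition device; the series invariant "identical aperture across
  frames" is also what makes the canthal line transferable). Full
  physiologic excursions are package constants: vertical excursion brings
  the iris edge exactly to the canthal line; full medial excursion carries
  the pupil inner margin 10 px past the punctum reference; full lateral
  excursion carries the iris outer margin 3 px past the lateral canthus.
  Only deficits relative to these constants are diagnostic, so the slack
  values set the healthy margin from each threshold (10 px and 3 px), not
  the decision rule itself.
* **Appearance.** Classes are painted with clinically plausible colors
  (near-white sclera, dark pupil, brown/hazel/blue iris with limbal
  darkening and radial fibres, pink LCP) plus seeded Gaussian noise, a
  smooth skin mottle and a specular glint. Inflammation cues are
  separable by design: redness shifts hue toward red in the affected
  band, swelling adds a blurred brightness bump. Real photographs add
  shadows, lashes, makeup, reflections and focus variation that the
  generator does not model, so passing tests demonstrate the correctness
  of the measurement chain, not clinical performance.
* **Prevalences** of the cohort default to a TED-clinic mix: upper
  retraction 0.36, lower retraction 0.42, motility disorder 0.32, lid
  redness 0.26, lid swelling 0.67, conjunctival redness 0.65,
  conjunctival swelling 0.18, LCP swelling 0.37.

## Quantitative rules

With landmarks from a (ground-truth or predicted) label mask:

* `D_up = (pupil_row − upper_margin_row) · mm_per_px`, likewise `D_down`;
  margins at the pupil column are medians over a ±3-column band to resist
  single-column raster noise.
* Upper/lower scleral show is the clipped distance between the visible
  iris extreme and the corresponding margin; the four-level category
  (normal / upper only / lower only / both) follows the sign pattern of
  the two shows.
* Rule thresholds: vertical-gaze iris overlap with the canthal line
  < 20 px is normal; medial gaze requires the pupil inner margin to pass
  the punctum reference (difference < 0 px); lateral gaze requires no
  residual scleral gap (≤ 0 px); a lower-minus-upper margin difference
  ≤ 1 mm flags upper retraction when the cornea is reasonably exposed
  (scleral show present or ≥ 80% of the expected iris disc visible);
  visible sclera below the inferior limbus flags lower retraction. The
  binary flags OR the scleral-show test with the margin rules, since the
  clinical criteria are stated side by side without precedence.
* The canthal line is recomputed in each gaze frame. In gaze frames
  (which have no LCP class) the canthus surrogates are the extremes of
  the whole aperture rather than of the sclera alone: at full medial
  excursion the iris occludes the medial corner, and the sclera extreme
  would be displaced by tens of pixels while the aperture extreme remains
  the fissure corner. In primary frames the medial canthus is the
  medial-most LCP pixel, per the clinical-standard conversion.
* Tie-breaks in extreme-pixel selection are deterministic: column
  extremes resolve by smallest row then column; row extremes (top/bottom
  of a region, whose tie set can be a wide flat arc) resolve to the
  median column, which stays on the region's axis of symmetry.
* Thresholds are applied in pixel space, as stated by the source
  criteria; millimetre equivalents are always reported through the
  measured calibration rather than an assumed resolution.

## Segmentation network

A U-shaped encoder–decoder. Encoder: 7×7 stride-2 convolution, 2×2 max
pooling, then three residual stages (the last two strided) — four
downsamplings, bottleneck at 1/16 resolution. Bottleneck context: a dense
atrous convolution block (four cascaded branches of dilated 3×3
convolutions, each closed by 1×1 convolution + ReLU, summed with the
input — summation chosen for the residual join) followed by residual
multi-kernel pooling (max pooling at four scales, 1×1 reduction to one
channel each, nearest upsampling, concatenation: C + 4 channels).
Decoder: four stride-2 transposed convolutions (kernel 4); at the first
three, the matching encoder map passes through a squeeze-and-excitation
block (reduction ratio r) and is added to the upsampled features
(addition rather than concatenation keeps the slim decoder narrow); a 1×1
convolution emits per-pixel class logits.

Defaults: widths (64, 128, 256, 512), r = 16, dilations (1, 3, 5), pool
sizes (2, 3, 5, 6) for 512×512 inputs. The desk-scale configuration used
throughout the tests is width-reduced to (12, 24, 48, 96) with r = 4 (16
does not divide 12; narrower stacks such as (8, 16, 32, 64) proved
unreliable at learning the thin caruncle-plica wedge, whose color overlaps
the inflamed eyelid band, across initializations) and scales the
context-block geometry with the input:
at 128×128 the bottleneck is 8×8, below the 11-pixel effective receptive
field of a dilation-5 kernel, so the slim config uses dilations (1, 2, 3)
and pool sizes (2, 3, 4, 6).

Training follows the stated recipe: Adam, initial learning rate 5e-4
decayed on a cosine schedule (to 1e-5), batch size 8, weighted
cross-entropy with foreground weights (1, 4, 4, 8) for
sclera/iris/pupil/LCP (background weight 1 — the listed weights cover
only the foreground structures, and weight 1 preserves their intended
emphasis), 30 epochs at desk scale, model selection by best validation
mean pixel accuracy. On-the-fly geometric augmentation (random horizontal
flip; rotation drawn uniformly in (−20°, +20°) applied with probability
0.5) follows the acquisition-augmentation recipe and regularizes the
small-structure classes.

The loss is implemented as the mean over pixels of `−w_y · log p_y`; MPA
averages per-class pixel accuracy over all classes including background,
with classes absent from both masks excluded as undefined rather than
scored 1.

## Classification network

A dual-branch multi-label classifier per structure crop. Branch 1:
strided stem, max pooling, a residual block, then a MobileViT-style block
(local 3×3 convolution, pointwise projection to an embedding, a
single-stage single-head transformer over the spatial tokens, pointwise
projection back, 3×3 fusion convolution over the concatenation with the
input) for global context. Branch 2: stacked strided 3×3 blocks whose
features are concatenated with branch 1's at each matching stage and
fused by 1×1 convolutions. The branch outputs are multiplied elementwise
(either branch can gate the other), reduced by a 3×3 convolution,
global-average pooled and mapped to one sigmoid output per label.

Choices left open by the source description: per-label binary
cross-entropy objective; matched spatial resolution between branches at
every fusion; a single transformer stage at the smallest MobileViT scale;
0.5 decision threshold; "normal" as the decision-level complement of the
positive labels rather than a trained output. Structure crops default to
256×256; tests use smaller crops (32–64 px) with widths (8, 16), which
suffice for the color/texture cues the generator produces.

## Numerical substrate

No deep-learning framework is a dependency: the networks run on a compact
reverse-mode autodiff engine over float32 numpy arrays (im2col + GEMM
convolutions; the transposed convolution reuses the convolution's
input-gradient kernel; max pooling with kernel = stride; nearest-neighbour
upsampling; batch normalization; layer normalization, softmax and batched
matrix products for the transformer stage). Every backward pass is
verified against central finite differences in the test suite. With a
fixed seed and single-threaded BLAS the training loop is exactly
reproducible; weights are He-initialized from an explicit generator.

Known numerical limits: exact horizontal-flip equivariance of the full
segmentation net is impossible because stride-2 window centers fall on
even columns, which a flip maps to odd columns; the equivariance check
therefore covers the stride-1 blocks, where it holds exactly with
symmetrized kernels.

## Problem sizes and protocol

The benchmark protocol (`tedeye.experiments`, driven by
`scripts/acceptance.py`) uses: a 200-eye cohort at 128×128 (0.25 mm/px)
split 8:1:1 for segmentation training; 100-eye cohorts at 512×512
(0.1 mm/px) for the rule-based retraction, motility and
distance-recovery benchmarks, with ground-truth masks feeding the
analytic stages (oracle mode) so the rules are measured in isolation from
model error. Diseased draws keep a margin from the thresholds (retraction
≥ 0.3 mm, gaze measures ≥ 5 px past threshold), mirroring the clearly
abnormal presentations the criteria target; rasterization limits accuracy
to about ±1–2 px, i.e. ±0.1–0.2 mm at the working resolution.

## Known limitations

* The generator's inflammation cues are low-dimensional (hue shift,
  brightness bump); a classifier trained on them says nothing about
  photographs of real inflammation.
* Eyelid arcs are parabolas; real lid contours are asymmetric, and ptosis,
  scleral show asymmetries or canthal tilt beyond small jitter are not
  modelled.
* The motility rules assume the head (and the canthal line) is fixed by
  the acquisition device; free-head photographs would need pose
  normalization first.
* Proptosis, diplopia and compressive optic neuropathy are out of scope,
  as is any composite activity score.
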