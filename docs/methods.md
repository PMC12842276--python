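# Methods

## The decomposition

Empirical mode decomposition (EMD) writes a finite real signal x(t) as

    x(t) = c_1(t) + c_2(t) + ... + c_n(t) + r_n(t)

where each intrinsic mode function (IMF) c_i satisfies two conditions:
its numbers of extrema and zero crossings are equal or differ by at most
one, and the mean of its upper (maxima) and lower (minima) envelopes is
zero at every point. The c_i are obtained fastest-first by *sifting*:
starting from the current residue h_0, iterate h_k = h_{k-1} − m_{k-1}
with m the envelope mean, until h_k is an IMF; subtract it from the
residue and repeat until the residue is monotone or no longer supports
two maxima and two minima. Because each IMF is subtracted exactly from
the running residue, the reconstruction identity holds to floating-point
rounding (observed ≲ 1e−15 relative RMS; tests require 1e−8).

The quasi-2D variant applied to an H × W × 3 RGB image flattens the
array row-major — channel varying fastest, then column, then row — runs
the 1D decomposition on the length-H·W·3 scan, and reshapes every IMF
back to image shape. The slow end of the decomposition (late IMFs, then
the residue) collects background illumination drift and other
low-frequency structure along the scan order; *enhancement* subtracts
the last k IMF images from the original, suppressing that background
while preserving local texture and contrast. This is deliberately not a
surface-based 2D EMD (no envelope surfaces or triangulation): the
flattened formulation is the method under study.

## Numerical choices

The defining conditions involve quantities that are exactly zero only in
the limit, so the implementation fixes tolerances (all configurable via
`SiftConfig`):

- **Envelopes.** Natural cubic splines through the extrema
  (`scipy.interpolate.CubicSpline`), with the two extrema nearest each
  end mirrored beyond the boundary (reflection about the first/last
  sample) before fitting, which suppresses end swings that would
  otherwise leak into late IMFs. With fewer than four knots the
  interpolant degrades gracefully to piecewise linear.
- **Extrema.** Interior neighbour comparison after plateau collapsing: a
  constant run strictly above (below) both neighbouring runs yields one
  maximum (minimum) at the run midpoint, lower index on even ties.
  Endpoints are never extrema.
- **Zero crossings.** Sign changes between consecutive samples; an exact
  zero inherits the previous nonzero sign, leading zeros are ignored.
  This counts a touch-and-go zero once and is plateau-safe.
- **Sift stopping.** Cauchy criterion SD = Σm² / Σh² < 0.2 (the
  classical threshold) *combined with* the IMF test, capped at 100
  iterations per IMF. A candidate that already passes both is returned
  unsifted. Hitting the cap is recorded (`converged=False`) rather than
  raised; the validity contract is "every IMF passes the test or carries
  the cap flag".
- **Zero-mean-envelope tolerance.** max |m| ≤ 0.05 × RMS(candidate).
- **Termination.** Decomposition ends when the residue lacks two maxima
  or two minima, when `max_imfs` is reached, when a candidate's RMS
  falls below 1e−12 of the input's (rounding noise on a flat residue is
  not signal), or when sifting exhausts the candidate's extrema before
  the IMF conditions can be met — in that last case the remaining weak
  oscillation stays in the residue, which is exactly the "residue counts
  differ by at most one" stopping condition.
- All arithmetic is float64 regardless of input bit depth; 8-bit
  conversion (clip or min-max rescale) happens only at export.

## Enhancement configurations

`EnhancementConfig` selects k IMFs counted from the slow end
(`subtract_from="last"`, the default — the named configurations NO /
IM-IMF-1 / IM-IMF-1-2 / IM-IMF-1-2-3 map to k = 0..3) or from the fast
end (`"first"`), with string shorthands `"all"` (enhanced = residue) and
`"all_but_first"` (keep the fastest IMF plus residue). The residue is
never subtracted unless `include_residue` is set: subtracting "IMFs"
means IMFs, and the residue carries the per-image mean level. The naming
is deliberately explicit because "the last IMF" is ambiguous between
extraction order and subtraction order; both directions are first-class.
`max_imfs` can cap decomposition depth (e.g. 3) but the default
decomposes fully — with full decomposition the residue is nearly
constant and the named configurations genuinely remove the slowest
oscillatory structure.

## Dataset preparation

`load_labeled_set` expects one directory per class and uses a fixed
8-class endoscopy label map (Polyps=0, Dyed-Resection-Margins=1,
Normal-Pylorus=2, Normal-Cecum=3, Esophagitis=4, Dyed-Lifted-Polyps=5,
Ulcerative-Colitis=6, Normal-Z-Line=7); custom maps are accepted.
Enumeration is lexicographic, so results do not depend on directory
order. Border cropping is automated (the reference procedure was manual)
as the maximal dark edge strip: edge rows/columns whose mean luminance
is below 10/255 are removed, with an all-dark fallback to the input.
Resizing is bilinear with anti-aliasing to 64 × 64.

The split is stratified per class: floor(0.4 n_c) to test, then
floor(0.3 · remainder) to validation, rounding remainders to train, with
a seeded shuffle. At 8 × 1000 this gives exactly 3360 / 1440 / 3200.
Stratification with a fixed seed is a design choice — the balanced
class layout makes stratified splitting the natural reading, and it
makes per-class partition sizes exact.

## Training protocol and Grad-CAM

`TrainConfig` encodes the training contract: Adam (lr 1e−3, weight decay
1e−3), ReduceLROnPlateau on validation loss (factor 0.1, patience 10),
batch size 32, 50 epochs by default, checkpointing whenever validation
loss decreases so that evaluation always uses the best-validation-loss
state. Full-size backbones are consumed through the
`ClassifierBackend` protocol and are not part of this package; the two
shipped backends are small numpy models implementing the same contract —
a softmax regression on flattened pixels, and a one-stage CNN with
frozen random 3×3 filters and a trained global-average-pool linear head.
The frozen-conv design keeps head training convex and deterministic
while still providing genuine spatial feature maps with analytic
class-score gradients, which is what Grad-CAM needs:
weight_k = spatial mean of ∂(score_c)/∂A_k, heatmap =
ReLU(Σ_k weight_k A_k), bilinearly upsampled and min-max normalized
(all-zero maps stay zero). The target layer is the backend's last (only)
convolutional stage.

## Synthetic fixtures: what they emulate and what they do not

Every generator returns machine-readable ground truth beside the data
and is deterministic per seed.

`make_synthetic_image` builds an image as base level + slow scan-order
sinusoid (background/illumination drift; default period = scan length/4)
+ fast scan-order sinusoid (texture; period ≤ 30 samples) + optional
Gaussian blob ("lesion") + optional Gaussian noise. Backgrounds
oscillate along the *flattened* scan order, not as 2D planes, because
the method operates in flattened space: separability must be posed there
to be testable by construction.

`make_synthetic_dataset` writes a directory-per-class PNG tree. Classes
differ by texture period (fixed phase, so the class signature is a
stable, linearly detectable pixel pattern) and by lesion placement and
channel mix. The confound is a slow background of amplitude
`confound_strength` whose phase follows a class-dependent mean (jitter
±π/2) with probability `confound_reliability` (default 0.75) and is
uniform otherwise: a high-amplitude, weakly class-correlated nuisance
emulating illumination drift that co-varies with acquisition conditions
without being diagnostic. At strength 0 there is no background at all.

The direction experiment (tests and acceptance script) uses 2 classes ×
30 images at 16 × 16, confound amplitude 80 with reliability 0.6, the
softmax backend at 15 epochs, and enhancement `k="all_but_first"`;
these sizes keep a 10-repeat experiment at desk scale while leaving the
mechanism intact. In this regime a raw-pixel linear model leans on the
dominant but unreliable background and lands around 70–90% test
accuracy, while the enhanced pipeline recovers the stable texture
signature and reaches ≳ 95%; the acceptance property is directional
(enhanced ≥ raw in ≥ 8/10 seeded repeats), matching the consistent —
not magnitude-calibrated — improvement the method claims.

What the fixtures do *not* emulate: photorealistic endoscopy (optics,
specular highlights, camera noise statistics), 2D-structured
illumination fields, inter-image registration, or deep-backbone
training dynamics. Passing tests therefore demonstrate that the
decomposition separates what it is constructed to separate and that the
pipeline's plumbing and direction-of-effect are sound — not that any
particular accuracy level transfers to real endoscopic data.

`make_prediction_fixture` draws (truth, prediction) label pairs with
per-class hit-rate targets and an optional error-routing matrix. Joint
per-class TPR *and* FPR targets are not independently satisfiable in
general (a class's false positives are other classes' routed errors),
so the generator takes TPR targets as primary; FPRs follow from the
routing and the class marginals.

## Evaluation stack

Metrics follow the one-vs-rest confusion-matrix definitions with 0/0
defined as 0 (a never-predicted class has precision 0 and F1 0, and is
flagged). Aggregates are overall accuracy and unweighted macro means —
with balanced classes macro and weighted averaging coincide, and the
averaging rule is stated here because summary tables rarely state it.
ROC/AUC uses the hard-label one-hot construction: one operating point,
three-point curve, AUC = (1 + TPR − FPR)/2 ≡ balanced accuracy. This is
a deliberate contract (probability-threshold curves are out of scope)
and the identity is asserted in tests. Cross-entropy is natural-log,
one-hot, mean-reduced, with probabilities clamped to [1e−12, 1].
Confidence intervals are percentile bootstrap over prediction rows
(B = 1000 by default, seeded); simulated coverage at nominal 95% is
checked to be ≥ 90% in the suite.

## Known limitations

- 1D sifting on a flattened image has no notion of vertical adjacency;
  rows are coupled only through the scan order. Horizontal structure
  dominates the separation, which is intrinsic to the quasi-2D design.
- Mode mixing: with broadband noise, blob-like structures scatter
  across IMFs, so enhancement can distort localized features even when
  it removes the background cleanly. The fixtures make this visible
  (the lesion's post-enhancement projection varies widely across
  seeds).
- The sift cap (100) is occasionally reached on rough random signals;
  such IMFs are flagged, not silently accepted.
- `enhance_batch` processes images independently; no attempt is made to
  harmonize decomposition depth n across a dataset, so "the last k
  IMFs" can refer to different absolute scales in different images.
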