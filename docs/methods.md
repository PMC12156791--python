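# Methods

`perifract` measures longitudinal change in peri-implant trabecular bone
structure from serial periapical radiographs. The measurement chain is:
rigid registration of each follow-up film to its baseline, extraction of
standardized mesial/distal regions of interest (ROIs) at the first implant
thread, reduction of each ROI to a binary trabecular skeleton, box-counting
estimation of the skeleton's fractal dimension (FD), and mixed-model
inference on FD change across an unbalanced follow-up panel. Because
patient radiographs of this kind cannot be redistributed, the package
carries a synthetic-data module with known ground truth; every stage is
validated against it.

## The fractal-dimension estimator

A binary mask is overlaid with square grids of tile size
s ∈ {2, 3, 4, 6, 8, 12, 16, 32, 64} px, anchored at the mask's top-left
corner. N(s) is the number of tiles containing at least one foreground
pixel (partial edge tiles count). FD is the negative slope of the ordinary
least-squares fit of log N(s) on log s; the fit's R² is reported alongside.
Closed forms pin the estimator down exactly: a single pixel gives FD 0, a
64-px line FD 1, a filled 64×64 square FD 2 with counts (64/s)², and a
level-5 Sierpinski carpet evaluated at the power-of-3 sizes gives
FD = log 8 / log 3 ≈ 1.8928 exactly, since N(3^k) = 8^(5−k).

Numerical conventions: the grid origin is fixed (no origin averaging), an
empty mask raises an error rather than returning 0, a perfectly flat
log-count line is reported with R² = 1 (a perfect fit, slope 0), and tile
sizes at or above the mask dimension contribute (log s, log 1) points, as
the classic ImageJ counter does. A `drop_oversized` flag restricts the
ladder to sizes below the mask's larger dimension.

**Window-size ceiling.** On a 10×30 window the occupancy bound
N(s) ≤ ⌈10/s⌉⌈30/s⌉ caps the fitted FD at ≈1.365 under the full ladder
(≈1.77 with oversized sizes dropped). Reported FDs from small clinical
ROIs therefore sit on a compressed scale and are comparable only within a
fixed window size and ladder — a caveat for comparisons across studies.
The package's texture-validation studies use 64×64 patches (cap ≈ 2.0),
where the estimator operates unconstrained; clinical runs keep the
standardized 10×30 ROI.

## The preprocessing chain

Each ROI patch passes through, in order: Gaussian blur (35×35 kernel),
subtraction of the blurred image from the original plus 128, binarization
at threshold 128 (≥ 128 → foreground, so an exactly flat field is
foreground), one 3×3 erosion then one 3×3 dilation (opening), perimeter
extraction (foreground pixels with a background 4-neighbor; outside the
border counts as background), and Zhang–Suen thinning to 1-px centerlines.
The bright, locally-above-mean phase is taken as trabecular bone.

Choices worth knowing:

* **Blur parameterization.** "Kernel size 35" is realized as a 35×35
  discrete kernel with σ = 35/6 (the ±3σ support convention). Legacy
  implementations disagree on the radius/σ mapping, so σ is an explicit
  parameter; the chain's invariances hold under any σ.
* **Brightness-shift invariance.** Stages run in floating point and the
  residual (original − blur + 128) is rounded to 10⁻⁶ before thresholding.
  The Gaussian kernel's weights sum to 1 only to ~10⁻¹⁶, so a global
  brightness shift c leaks into the residual at ~c·10⁻¹⁵; rounding far
  above that floor and far below any real intensity difference makes the
  binary output *bit-identical* under any global shift that avoids
  saturation. This is the property that lets films with different
  exposures be compared, and it is asserted exactly in the tests.
* **Thinning.** Zhang–Suen thinning occasionally leaves a 2×2 foreground
  block; a deterministic cleanup deletes one corner of each such block
  (connectivity is preserved through the diagonal), so skeletons satisfy a
  strict no-2×2 thinness property.

## Registration and ROI placement

Serial films taken with a paralleling device differ by small in-plane
shifts and rotations, so alignment uses a rigid transform (translation +
rotation about the image center), found by Powell minimization of the mean
squared intensity difference over a coarse-to-fine pyramid (2× block-mean
levels, coarsest ≥ 32 px). On noiseless phantoms with known jitter up to
±10 px / ±5°, recovery errors are in the 10⁻³ px/degree range; the
optimum's objective value is attached to the transform so before/after
alignment quality is inspectable. Follow-ups are resampled (bilinear) into
the baseline frame, and ROI pixel values are read from the resampled
image, so a single ROI spec per patient-side applies to every visit.

ROI placement is a deterministic search: the 10×30 window (long axis along
the implant) whose inner-edge midpoint is nearest the anchor point — the
implant margin at the first-thread row, or the CEJ-line endpoint for
control teeth — subject to staying on its own side of the anchor, inside
the image, and clearing the exclusion mask (implant threads, adjacent
teeth, lamina dura, ligament, crest, roots) by ≥ 1 px. Ties break toward
the crest. The exclusion mask is supplied, not auto-segmented. Minimality
of the chosen placement is verified in tests against a brute-force scan of
all admissible windows. Control-tooth ROIs are placed with the same rule
against the CEJ-line endpoints (immediately apical when the abutting spot
is blocked); no extra apical offset is applied.

## The synthetic-data generator

Trabecular texture is a fractional-Brownian surface synthesized spectrally:
white noise filtered by f^−(H+1) amplitude (power spectrum f^−(2H+2)),
normalized, then scaled to the requested mean gray and contrast. The Hurst
exponent H ∈ (0,1) is the one-knob complexity control — lower H, rougher
texture, higher downstream FD. Two features make the phantom behave like a
radiograph rather than raw noise:

* **Imaging PSF** (`psf_sigma`, default 1.5 px): a Gaussian blur modelling
  focal-spot and film/scanner blur at 300 dpi. It band-limits the texture
  so trabecular grain spans several pixels. This matters: without it the
  grain is subpixel, the 3×3 opening erases exactly the high-frequency
  structure that distinguishes rough from smooth textures, and the H→FD
  relationship inverts. With the PSF, median pipeline FD decreases
  strictly across H ∈ {0.2, 0.5, 0.8} (20 seeds) and all values fall
  inside the plausible trabecular band [1.3, 1.9] on 64×64 validation
  patches.
* **Padded-canvas misalignment.** Follow-up views are rendered on a canvas
  padded by 24 px, rigidly warped about the shared center, and
  center-cropped, so texture flows in from beyond the crop instead of a
  zero-filled wedge — as bone extends beyond the field of a repositioned
  film. The crop shares the canvas center, so the applied transform is
  also the ground truth in the cropped frame.

Longitudinal complexity drift is injected by re-rendering each patient's
texture with the *same* spectral phases and a per-visit Hurst offset:
serial images look like the same bone with altered complexity, and the
signal rides on texture structure, not luminance. Brightness jitter and
per-visit detector noise are applied after the warp. An implant is drawn
as a near-saturated vertical profile with a sinusoidal thread
(radius 8 px, pitch 12 px, depth 2 px by default).

The default study panel is an unbalanced 77-patient follow-up design with
215 visit records (per-month N of 77/31/64/43 at 0/3/6/12 months), built
from blocks 25×{0,3,6}, 34×{0,6,12}, 8×{0,12}, 5×{0,3}, 4×{0,6},
1×{0,3,6,12}. Misalignment defaults to SD 3 px / 2°, brightness jitter to
SD 5 gray levels — plausible for paralleling-device periapicals; both are
parameters, as no empirical measurement of inter-visit jitter was
available.

What the generator does *not* emulate: projection geometry, scatter,
anatomy other than the implant silhouette, and any real-bone microstructure
beyond its second-order spectral statistics. Passing tests therefore show
that the measurement chain recovers what it is designed to recover under
controlled conditions — not that FD tracks remodeling in real patients.

## Statistics

FD per visit is the exact mean of the mesial and distal ROI dimensions (a
side with an empty skeleton leaves the record flagged incomplete rather
than silently averaged). Inference uses a linear mixed model with a
per-patient random intercept, time as a categorical factor referenced at
baseline, jaw/sex as binary factors and age continuous; a GEE variant with
exchangeable working correlation is available behind the same interface,
as "Wald χ²" reporting is typical of GEE output. Wald chi-squares are
computed from the fixed-effect estimates and their covariance, so both
model variants share one contrast path: per-month contrasts against
baseline (df 1) and joint tests per effect. Pairwise contrasts are
reported unadjusted with a Holm-adjusted column alongside. Independent
groups are compared with Welch's t-test by default (Student's optional);
SDs use the n−1 denominator throughout.

Calibration, measured by simulation at the default panel (record-level
generator: random intercept SD 0.15, within-patient SD 0.05 around a
baseline mean of 1.55): each baseline contrast's type-I error is within
0.05 ± 0.02 over 500 null replicates, and injected effects (month-12
offset +0.08, mandible−maxilla jaw effect +0.19) are recovered with bias
below 10% of the effect. These simulation sizes (500 null / 200 effect
replicates in the test suite; 300/150 in the acceptance script) keep the
Monte-Carlo error a small fraction of each tolerance.

## Known limitations

* Fixed-origin box counting makes FD sensitive to sub-tile translations;
  the effect is bounded (tested) but not removed by origin averaging.
* The 10×30 clinical ROI compresses the FD scale (ceiling ≈ 1.365 under
  the full ladder); use `drop_oversized` or larger windows for
  texture-physics questions.
* Registration assumes in-plane rigid motion; out-of-plane projection
  changes are not modelled.
* Exclusion masks are supplied by the operator; no automatic segmentation
  of implant threads or anatomy is attempted.
* Whether follow-ups should be registered to baseline or mutually is
  unresolved in the underlying protocol; baseline-as-fixed is implemented.
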