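# Methods

`organovote` re-implements, as a tested pipeline on synthetic data, a
label- and test-free strategy for classifying colorectal-cancer patients
into High- and Low-CEA groups (serum CEACAM5 above/below 2.5 ng/mL) from
nothing but bright-field morphology of their patient-derived organoids
(PDOs): per-organoid features → per-organoid random-forest classification
→ majority-vote aggregation into one patient-level call → binomial theory
of how patient-level accuracy scales with panel size.

## Synthetic cohort model

Real PDO image libraries for this problem are not publicly deposited, so
the package ships a generator that emulates their statistical structure.
Each organoid carries a latent discriminant

    z = s·Δ/2 + u + e,   s = ±1 by patient class,
    u ~ N(0, σ_p²) per patient,   e ~ N(0, 1 − σ_p²) per organoid,

with σ_p = 0.25·Δ. The marginal per-class law of z is N(±Δ/2, 1), so the
optimal single-organoid rule (z > 0) is correct with probability Φ(Δ/2);
`calibrate_separation(a)` returns Δ = 2·Φ⁻¹(a) to hit a requested
single-organoid accuracy. The 25% patient-effect fraction makes organoids
within a patient correlated — patient-level voting is therefore a
genuinely harder problem than i.i.d. voting — while keeping the
calibrated accuracy regimes reachable.

Features derive from z:

* **area** (µm²): log-normal, `ln A = µ + σ_ln·z` with (µ, σ_ln) set by the
  mean diameter (default 200 µm) and the platform's area CV — 0.18 for the
  uniform arrayed platform ("Eba"), 0.71 for conventional dome culture
  ("Std"), the day-21 uniformity statistics the analysis is premised on.
  A log-normal is used because organoid areas are strictly positive and
  right-skewed.
* **circularity**: platform baseline (0.93 Eba, 0.78 Std) plus a small
  negative slope on z plus Gaussian noise, clipped to (0.15, 1]. It
  carries class signal, but only through z, so the pair (area,
  circularity) has exactly the calibrated Bayes accuracy — the classifier
  cannot exceed the calibration by pooling features.
* **perimeter**: the deterministic identity P = √(4πA/C), preserving the
  circularity definition exactly.

Class effect defaults to 0: with no separation requested the pooled area
CV equals the platform CV, which is what the dispersion calibration
checks measure. Serum CEA values are decorative (consistent with the
class by construction) and carry no feature information.

What the generator does **not** emulate: real optics (focus, debris,
illumination gradients), multi-organoid fields, lumen/texture structure,
non-Gaussian patient effects, and any mechanistic link from CEACAM5
biology to morphology — class separation is purely phenomenological.
Passing tests therefore demonstrate that the pipeline's statistics and
plumbing are correct, not that morphology predicts CEA status in real
cohorts.

Rendered images are dark ellipses (optionally roughened by low-order
boundary harmonics) on a light noisy background, row-major with origin
top-left, 8-bit grayscale, 2 µm/pixel by default; the ground truth stores
the analytic area/perimeter of the noiseless boundary polygon. All
randomness flows from one seeded `numpy` generator per call; image
rendering derives a per-organoid stream from (seed, CRC32 of the organoid
id), so outputs are byte-identical across runs.

## Morphometrics

One organoid per image is assumed. Segmentation: global Otsu threshold,
keep the dark side, fill holes, keep the largest 8-connected component
(error if below `min_size`). Features follow the imaging-program
conventions: area = pixel count × pixel_size²; perimeter = length of the
sub-pixel 0.5-level marching-squares contour; circularity = 4πA/P²,
clamped to 1, with values beyond 1.05 rejected as measurement defects.

The raw marching-squares polygon of a binary mask staircases along
oblique boundaries and overestimates perimeter by ≈5%, biasing disc
circularity down to ≈0.90. The contour is therefore simplified by
Douglas-Peucker at 1 px tolerance before measuring its length: staircase
vertices are removed while true corners survive. On analytic fixtures
this gives disc ≈ 0.99, axis-aligned square ≈ 0.80 (ideal π/4 ≈ 0.785),
and 2:1 ellipse ≈ 0.835 against the Ramanujan-perimeter oracle 0.841. A
Crofton estimator was considered and rejected: it underestimates an
axis-aligned square's perimeter by ≈6%.

Quantile convention everywhere (quartiles, fences, trimming): linear
interpolation between order statistics (`numpy.percentile` default).

## Classification and majority voting

The per-organoid classifier is a random forest on (area, perimeter,
circularity): 100 trees, unlimited depth, √p features per split, balanced
class weights, seed 0 — standard defaults, recorded in the model's JSON
metadata sidecar. Trees are scale-invariant so features are not scaled;
evaluation follows a three-tier protocol (resubstitution on the training
batch, a new batch from the same patients, a cohort of new patients)
rather than cross-validation. Per-class accuracy is recall with High-CEA
as the positive class.

A patient-level call aggregates a panel of that patient's organoids:

1. **Tukey-fence filtering** per feature — drop any organoid with any of
   the three features outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]. Filtering is
   applied per patient at prediction time. On near-Gaussian data these
   fences remove ≈0.7% of records; a percentile-trimming alternative
   (`trim_tails_filter`, e.g. 12.5% per tail) is provided for workflows
   that trim a fixed fraction instead, since no IQR rule can remove
   12.5% per tail from well-behaved data.
2. **Truncation** to at most 49 organoids (a seeded uniform shuffle, so
   the choice is reproducible but not order-biased). 49 is the reference
   panel size: odd, so strict-majority ties are impossible.
3. **Strict majority vote** over the per-organoid predictions. An exact
   tie (possible only for even panels) is reported as Indeterminate and
   scored as incorrect — a conservative policy that never manufactures a
   call.

## Voting theory

With independent per-organoid accuracy p and panel size n, the
patient-level accuracy is the binomial tail P[X > n/2], X ~ B(n, p) —
the Condorcet jury mechanism. The exact tail is evaluated with
`scipy.stats.binom.sf` (regularized incomplete beta, numerically stable
at any n; an explicit log-space summation would be redundant). A
hand-written Monte-Carlo resampler provides the independent second route;
the two are cross-checked within 3 binomial standard errors, and the
exact route is itself tested against brute-force pmf summation.

At the reference panel of 49: p = 0.64 → 97.8% (≈98%), p = 0.37 → 3.1%
(≈3%) — quantitatively, why a uniform platform whose Low-CEA organoids
are classified correctly only 64% of the time still yields near-certain
patient calls, while a heterogeneous platform at 37% is driven towards
certain *mis*classification as panels grow. The four reference regimes
{0.86, 0.64, 0.81, 0.37} are bundled as `PAPER_REGIMES`.

## Drug response

Survival fraction = 100 × (day-6 luminescence, drug) / (day-6
luminescence, DMSO control). The dose-response AUC is the trapezoidal
mean of percent survival over log10(concentration), normalized by the
log-span: a flat 100% curve scores 100, the value is bounded by the
survival range, and it is invariant to rescaling all concentrations by a
common factor — making AUCs comparable across dose ranges. Group
comparison reports mean ± SEM per class and a Welch two-sample t
(descriptive; no multiplicity correction). No IC50/4PL fitting is
attempted.

## The one-command study

`run_paper_experiment` (CLI: `organovote paper`) mirrors the full design:
a five-patient training cohort (3 High, 2 Low) with training +
same-patient validation batches, a seven-patient external cohort (3 High,
4 Low), 49 organoids per patient per batch, per-platform forests,
majority-vote calls on every tier, and the four reference voting curves.
The uniform platform is calibrated to single-organoid Bayes accuracy
0.86 and the heterogeneous platform to 0.60; the historically reported
asymmetric per-class accuracies are artifacts of a particular fitted
model on real images and enter this package only as voting-theory
inputs. Every stage writes a JSON run manifest (config, seeds, paths,
version, timestamps), filter counts are always logged, and identical
seeds reproduce identical reports.

## Numerical and testing choices

* Problem sizes: dispersion checks use 10,000 draws (Monte-Carlo SE on
  the CV ≈ 0.2%); classifier regime checks use 40 patients × 25 organoids
  per batch; the pipeline test runs 15-organoid batches. These sizes put
  sampling error well inside the asserted tolerances while keeping the
  suite fast.
* The Bayes-calibration property is asserted on 200-patient cohorts: with
  only a handful of patients the realized patient random effects dominate
  the marginal accuracy, by construction.
* Strict monotonicity of the exact tail in p is asserted away from the
  extremes, where the tail saturates to 0/1 in double precision.
* Degenerate inputs error loudly: single-class training tables, unlabeled
  evaluation rows, constant vectors in correlation, empty vote lists,
  sub-4-record panels for quartile fences, non-increasing concentration
  grids, nonpositive control luminescence.

## Known limitations

Absolute feature values from real micrographs are not reproducible here
(thresholding and scale settings of the original interactive workflow are
unknown); only the synthetic render→segment→measure round-trip is
validated. The voting model assumes conditionally independent
per-organoid errors given the patient; strong within-patient error
correlation would flatten the accuracy-vs-panel-size curves faster than
the binomial theory predicts. Multi-organoid image tiling, soft
(probabilistic) voting, and multi-class extensions are out of scope.
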