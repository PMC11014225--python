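# Methods

This note documents the models, algorithms and design choices behind
`breathpanel`: what the synthetic cohorts contain, how traces become a
feature matrix, how the biomarker panel is selected and evaluated, and
what the package's passing tests do and do not establish about real
breath data.

## 1. Generative model of a breath chromatogram

One simulated breath sample is

```
x(t) = b(t) + Σ_c  EMG(t; μ_c, σ_c, τ, A_c) + ε(t),     t ∈ [0, 800] s at 10 Hz
```

* **Peak shape.** Each detectable compound elutes as an exponentially
  modified Gaussian (EMG): a Gaussian of width `σ_c` convolved with an
  exponential tail of constant `τ` (column/detector tailing). The EMG is
  the standard phenomenological model of a tailed GC peak. Width grows
  linearly along the run, `σ(rt) = 0.8 + 0.0015·rt` seconds. The slope
  is chosen so that the late-eluting compounds of the shipped library
  (entries 6–9 s apart beyond 600 s) remain chromatographically
  resolvable, as they evidently were on the platform that identified
  them; a steeper growth makes half the library co-elute into single
  detected peaks.
* **Compound positions.** The 61 identified breath VOCs of the packaged
  library elute at their library retention times. In addition,
  `n_unknown` (default 60, co-elution-limited to ~45 placed)
  unannotated compounds are placed once per cohort at random slots with
  a resolution-aware minimum separation `max(7 s, 2.5σ(rt))`; real
  breath runs detect roughly 100 VOCs of which only 61 carry an
  identification, and the unknowns close that gap.
* **Abundances.** Peak areas are log-normal per compound per sample:
  `log A_c ~ N(amp_log_mean, amp_log_sd²)` with defaults (0, 0.5²). In
  cancer samples the three planted biomarker compounds
  (2,4-dimethylhexane at 197 s, 2,5-dimethylheptane at 341 s,
  2,2,5,5-tetramethylhexane at 470 s) have their mean log-amplitude
  raised by `effect_size · amp_log_sd` (default effect size 1.5). A mean
  shift in log space is the simplest model of "elevated abundance" that
  keeps areas strictly positive.
* **Retention-time jitter.** Each sample draws a global shift
  `N(0, 1 s²)` (injection timing) and each peak an independent
  `N(0, 0.5² s²)` jitter.
* **Detection.** Every non-biomarker compound appears in a given sample
  with probability 0.9; the biomarkers always appear.
* **Baseline and noise.** `b(t)` is a slow positive drift (two
  incommensurate low-frequency sinusoids) with amplitude 5% of the
  reference peak height (the apex height of a median-amplitude mid-run
  peak); `ε(t)` is white Gaussian noise with standard deviation 2% of
  the same reference (apex SNR ≈ 50 for a median peak, chosen as typical
  for a photoionization detector trace in routine operation).
* **Technically inadequate runs.** `inject_inadequate` corrupts a
  requested fraction of samples by one of three modes: (a) global
  intensity collapse (×10⁻³), (b) detector saturation (clipping at the
  sample's own 90th intensity percentile, flattening ~10% of points),
  (c) removal of the landmark peaks (linear interpolation across ±8 s
  windows at the ten most abundant consistently present compounds).

The cohort manifest assigns the first 18 samples of each group (in
manifest order) to the training set; with the default 36 + 32 cohort this
reproduces an 18+18 training / 18+14 testing split. A flag allows random
within-group splitting instead.

**What the generator does not emulate:** batch/day drift (the emulated
study collected everything in one setting), compound-compound abundance
correlations, detector nonlinearity, true co-elution chemistry
(overlapping peaks simply add), and demographic confounders. Passing
tests therefore demonstrate correctness of the analysis pipeline under
the stated statistical model — not that three specific compounds
discriminate cancer in any particular human cohort.

## 2. Pre-processing

* **De-noising** is Savitzky–Golay (moving least-squares polynomial)
  smoothing, window 21 samples (2.1 s), order 3. The filter reproduces
  any locally cubic signal exactly, so resolved peaks keep their apex
  and area while white-noise power drops.
* **Baseline** is asymmetric least squares: iteratively solve
  `(W + λ D₂ᵀD₂) z = W y` with weight `p = 0.01` above the current
  baseline and `1 − p` below (10 iterations, pentadiagonal system solved
  with a banded Cholesky factorization). The smoothness default is
  `λ = 10⁹`: the Whittaker penalty acts on second differences of
  *samples*, so the effective stiffness length is `λ^{1/4}` grid steps
  (~18 s at 10 Hz) and the appropriate `λ` scales with the fourth power
  of the sampling rate — values quoted for ~1 Hz detectors are about
  four orders of magnitude smaller. Negative residuals are kept, not
  clipped, so integration stays unbiased.
* **Quality control** flags a run as technically inadequate when any of
  three criteria fire: total (positive-part) signal below 1% of the
  cohort median; more than 5% of points at or above the saturation
  ceiling (default: 99.9% of the trace's own maximum, which detects
  flat-topped clipping without an absolute calibration and is invariant
  under rescaling); or fewer than 2 of the 6 landmark (anchor) peaks
  found within ±3 s of their shift-corrected positions. Anchors are the
  most abundant, consistently present, well-isolated library compounds,
  estimated from the cohort by robust medians so that a minority of
  corrupted runs cannot move them. Two design points deserve note:
  * the anchor search compensates the sample's global retention shift
    (estimated by the same voting procedure as alignment, bounded to
    ±4 s) — otherwise legitimately shifted samples fail the check;
  * the threshold is 2-of-6 rather than a majority: with per-compound
    detection probability ~0.9 a genuine sample occasionally lacks
    several landmark compounds, and 2-of-6 keeps the false-flag rate
    negligible (~10⁻⁵ per sample) while anchor-stripped traces still
    count zero.

## 3. Peak extraction and the feature matrix

* **Detection.** Local maxima with prominence ≥ 3 times the robust noise
  level, apex height ≥ 5 times the noise level, and width ≥ 5 samples at
  half prominence (real peaks span tens of samples at 10 Hz; narrower
  maxima are baseline-flex or noise artifacts). Noise is estimated from
  the median absolute deviation of *second* differences — first
  differences see the slopes of a crowded trace and overestimate badly.
  Prominences are evaluated in a ±25 s window so an isolated tall peak's
  base cannot wander across unrelated peaks.
* **Integration** is trapezoidal between bounds tightened to where the
  trace falls below 1% of apex height (or twice the noise level), and is
  *valley-referenced*: each peak is integrated above its local pedestal,
  the median trace level at its prominence bases. In a trace with ~90
  peaks over 800 s the EMG tails overlap into a continuum that no
  run-level baseline can subtract correctly everywhere; referencing each
  peak to its own local floor — what chromatographic integrators call
  baseline-to-valley integration — removes the residual bias (measured
  isolated-peak median area error improves from −8% to −1%).
* **Alignment.** Each sample's global retention shift is estimated
  against up to 12 anchor compounds by consensus voting: every
  apex-to-anchor offset within ±8 s is a candidate, the offset grid value
  consistent with the most anchors wins (ties toward zero), and the
  final shift is the median of the winning matches. A plain
  nearest-match median is poisoned when a strongly shifted sample's
  anchors lie closer to *neighbouring* compounds; voting reduces the
  shift error SD from ~1 s (no correction to speak of) to ~0.25 s.
  Shift-corrected apexes are pooled over samples and single-linkage
  clustered, splitting where the gap between neighbours exceeds 3 s;
  clusters present in at least half the samples become consensus
  features. With the default cohort this yields 80–87 features —
  bracketing the ~100-VOC scale of a real run once co-eluting library
  pairs (a dozen entries lie within 6 s of a neighbour) have merged.
* **Annotation** assigns each consensus feature the nearest library
  compound within ±3 s, one-to-one, closest first, ties toward the
  smaller retention time. Duplicated compound names carry an ``@<rt>s``
  qualifier.
* **Feature values** are `log10(area + ε)` with `ε` set to 1% of the
  smallest positive area (which also imputes absent peaks, preserving
  "absent = low" semantics), then centered and scaled per feature using
  the **training rows only**. The fitted transform is stored alongside
  the matrix; permuting test rows provably leaves training-row values
  unchanged (asserted as a test).

## 4. Panel discovery

The classifier is a two-class Fisher discriminant written from first
principles: pooled within-class covariance `S` (denominator n − 2),
shrinkage `S_λ = (1−λ)S + λ (tr S / p) I`, weights
`w = S_λ⁻¹ (μ₊ − μ₋)`, threshold at the projected midpoint of the class
means (equal priors — the training sets are balanced by design). A score
exactly at the threshold classifies positive. `λ = 0` reproduces textbook
LDA and is used in the oracle tests; `λ = 0.1` is the default for
3-feature fits at n = 36, as numerical insurance.

Panels are selected by exhaustive search: every k-feature subset of the
candidate pool (k = 3 by default; C(100, 3) = 161,700 is well inside the
10⁶-subset budget) is scored by leave-one-out cross-validated accuracy on
the training rows. Ties are broken by the larger full-training-set Fisher
separation `J = Δμᵀ S_λ⁻¹ Δμ`, then by the lexicographically smallest
index tuple, making the ranking deterministic. Leave-one-out is the
natural choice at n = 36; a forward-selection (greedy) mode with the same
scorer is available for larger k. The search engine evaluates subsets in
vectorized batches — removing one sample shifts its class mean in closed
form and downdates the pooled scatter by a rank-one term, so all n folds
of all subsets are solved as stacked k×k systems; the engine is asserted
to make bit-identical decisions to the reference one-model-per-fold loop.

**Known limitation — selection optimism.** With ~100 candidate features
and 36 training samples, LOOCV accuracy saturates: at a planted effect of
2.5 pooled-SD units, hundreds of panels containing only two of the three
true markers tie at or above the true panel's score, and the tie-break
statistic J is itself subject to winner's curse (chance marker–noise
correlations inflate `Δμᵀ S_λ⁻¹ Δμ` across ~300 competitors). The
consequence, reproduced by the panel-recovery test, is that the full
planted triple is top-ranked in only a minority-to-half of runs even at
effect sizes where each marker is individually obvious, and held-out
accuracy is systematically below training accuracy. This is a property
of small-cohort exhaustive panel selection itself, not of the
implementation; the null-calibration test confirms that with no planted
effect the held-out accuracy stays at chance (mean ~45–50% over 50
cohorts), i.e. the optimism never leaks into the test set.

## 5. Evaluation

Confusion counts are tabulated per evaluation set (training, testing,
combined; combined counts are cell-wise sums by construction) and derived
percentages — sensitivity, specificity, positive and negative predictive
value, total accuracy — are rounded half-away-from-zero to one decimal.
Ratios with a zero denominator are reported as NaN, never as 0. The PCA
projection of the selected panel is computed by eigendecomposition of the
training-row covariance (components orthonormal, largest-magnitude
loading positive, explained-variance fractions summing to one); test rows
are projected into the training frame, with a flag to refit on all rows.

## 6. Reproducibility and problem sizes

All randomness flows from a single integer seed through
`numpy.random.Generator`; rerunning any stage or the whole pipeline with
the same configuration is byte-identical, and the stages communicate only
through files, so the CLI subcommands compose exactly. The test suite
works at deliberately modest scales chosen for a laptop-class machine:
unit tests use a 3-compound, 120-s mini-cohort; the cohort-level checks
use one full default cohort; panel-recovery and null-calibration Monte
Carlos use 20 and 50 replicate cohorts respectively (the null runs the
complete trace-level pipeline; the recovery study samples the feature
matrix directly from the amplitude law, which is the same test statistic
without the trace-rendering cost).

## 7. Other limitations

Retention times are taken from the library as givens — there is no
physical retention model, and no two-dimensional separation; co-eluting
compounds are not deconvolved (merged features carry the joint area);
QC criteria are this package's operationalization of "technically
inadequate", not a reconstruction of any instrument vendor's rules; and
the diagnostic evaluation implements a single train/test split, not
repeated cross-validation or a prospective blinded phase.
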