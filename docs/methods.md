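# Methods

This note documents the models and procedures implemented in `mrmscreen`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Data model

A chromatogram is a strictly increasing retention-time grid (minutes) with
relative intensities, tagged with an integer MRM transition channel and
optional sample metadata. All channels of one sample are expected on one
grid (readers resample onto the first channel's grid by linear interpolation
when they differ); the TIC is the elementwise channel sum. Intensities are
arbitrary relative units throughout — no attempt is made to convert to
concentrations.

The packaged transition table lists the ten chlorine-homolog MRM mass
transitions (precursor/product m/z) used for PCB screening; it is metadata
only and never enters the numerics.

## Pre-processing

**Savitzky–Golay smoothing.** Each point is replaced by the centre of a
least-squares polynomial (order N) over a 2d+1 window; edge points come from
evaluating the first/last full window's polynomial at the edge offsets
(`scipy.signal.savgol_filter`, `mode="interp"`). Defaults d=5, N=3 (an
11-point cubic): wide enough to suppress single-sample noise, narrow enough
that a peak with Gaussian width parameter c ≈ 0.02 min on a 0.005-min grid
loses well under 5% of its apex. The filter is linear, so corrections
commute with channel summation.

**Baseline.** The trace is cut into consecutive windows of 400 samples
(2 min on the default grid); the 0.05 quantile of each window becomes a knot
at the window's central retention time, the first/last knots are duplicated
at the trace ends, and a monotonicity-preserving piecewise cubic
(`PchipInterpolator`) through the knots — clipped below at 0 — is subtracted,
with negative residuals clipped to 0. The low quantile makes knots
insensitive to peaks occupying a small fraction of a window; PCHIP avoids
the overshoot a natural spline would put under tall peaks. Knot placement at
window centres and the end duplication are our choices; the window/quantile
defaults follow common practice for column-bleed backgrounds and are
configurable.

**Alignment.** One rigid shift per channel: Δ = (calibration standard rt) −
(sample standard rt) using the first listed standard of the channel, with
intensities re-interpolated onto the original grid (edge values extended).
Rigid shifting assumes drift is dominated by a run-level offset; no warping
is attempted, so nonlinear drift along the run is a known limitation.
Whether one shifts labels or resamples intensities is equivalent up to
interpolation error; resampling keeps every trace on the common grid.

Order is fixed: smooth → baseline → align.

## Peak fitting

Regions are maximal half-open intervals where the corrected intensity stays
at or above `min_height` (default 50 relative units ≈ 5× the default noise
floor), merged across gaps shorter than `min_gap` (0.10 min). Each region is
modelled as y(x) = Σ βᵢ exp(−((x−Bᵢ)/cᵢ)²); the reported width is the c
parameter (σ = c/√2), height Θ = β, area p = β·c·√π. Fitting uses bounded
trust-region least squares (β ∈ [0, 2·max], B inside the region, c between
one grid step and the region span). Initial centroids sit on the n tallest
local maxima, with any missing centroids spread evenly over the signal's
support (samples above 25% of the region maximum) — spreading over the full
region instead lets coeluted pairs collapse into one wide component.
Initial widths are support-span/(2n), amplitudes the trace values at the
centroids.

The component count starts at the number of calibration congeners expected
in the region (floor 1) and grows until the goodness of fit
R² = 1 − SSE/SST reaches `gof_target` (default 0.90) or `n_max` (default 6)
is hit, in which case the best attempt is returned flagged unconverged.
Components below 0.1% of the region maximum are pruned and the R² is
recomputed on the pruned model. R² is undefined (an error) for constant
observed regions; all-zero regions return an empty unconverged result rather
than raising, since they occur routinely on quiet channels.

Note the stopping rule is a goodness-of-fit rule, not a model-selection
rule: when a single Gaussian already explains ≥ 90% of the variance of a
lightly coeluted bump, iteration stops at one component by design. Forcing
the resolution of a known pair is done by seeding the fit with the
calibration-informed count.

## Classification

Features per peak: signed Δrt to each of three designated injected
standards, plus the MRM channel id. Which three standards are designated is
a configuration choice (the pipeline uses the three calibration standards of
the reference channel, sorted by rt); reported accuracies depend on it.
Channel is nominal: trees take it raw, SVM and naive Bayes see it one-hot
encoded. The SVM (RBF, C=10) gets standardized Δrt features; naive Bayes
takes Δrt raw — per-class variance estimation makes scaling redundant — with
`var_smoothing=1e-2` so that a (class, channel) cell empty in training
cannot veto its class through a near-zero variance. Random forest: 100
trees, √features per split, unlimited depth. All estimators are seeded.

Splits are by sample (never splitting one sample's peaks), either random
toward an 80/20 target or by explicit location holdout. Cross-validation is
7-fold, stratified by class when every class has at least 7 members, plain
shuffled folds otherwise.

Association labels in the pipeline are defined geometrically: a peak's
label is the calibration congener on its channel with the nearest retention
time — the rule an analyst applies when reading a peak off against the
calibration run. Peaks within 0.15 min of a designated standard are excluded
from classification, mirroring the exclusion of injected standards from
downstream intensity summaries.

**Present/absent scoring.** A congener is "found autonomously" in a sample
exactly when an annotated peak was selected for it; confusion counts against
a reference (here: the generator's ground truth, in the field: manual
analysis) follow TP = found by both, TN = by neither, FP = autonomous only,
FN = manual only, over the full (sample × class) universe, with accuracy,
precision P = TP/(TP+FP), recall R = TP/(TP+FN) and F1 = 2PR/(P+R) (0 when
P+R = 0 by convention; zero-denominator metrics raise unless explicitly
converted to 0).

## Annotation, non-targets, templates

The target peak of a class in a sample maximizes
G = √((Θ/Θ₀)² + (p/p₀)² + 1/max(|t−r_j|, ε)²). Height and area are rescaled
by the calibration run's maximum fitted height Θ₀ and area p₀ because the
three terms carry incompatible units; without rescaling the reciprocal-rt
term either dominates or vanishes depending on the intensity scale. ε
(default: one grid step) bounds the rt term for peaks essentially at r_j —
below ε, rt differences are not meaningful on the grid anyway. Ties break
deterministically: smaller |t−r_j|, then larger height, then lower rt.
For well-aligned data the rt term dominates, which is the intended priority;
height and area decide between heavily coeluted candidates at similar Δrt.

Non-target screening considers peaks classified to a class but never
selected for it, clusters them per class along rt by single linkage (link
when consecutive rts are within a tolerance, default 3 grid steps), and
reports clusters present in at least `min_occurrence` (default 0.5) of the
samples with their mean rt and distinct-sample occurrence fraction.

Location templates average annotated-peak heights per class over a
location's samples, counting samples without the class as zero and dividing
by the location's total sample count; areas can be averaged instead behind a
flag. Standards never enter (they are excluded before classification).

## Synthetic generator

`simulate_batch` emulates exactly the degradations the pipeline corrects:
Gaussian congener peaks, additive Gaussian noise (sd 10 against target
heights 200–700, i.e. peak SNR ≥ 20), a linear-plus-exponential column-bleed
baseline, one rigid uniform(−0.3, 0.3) min shift per sample applied to peaks
and standards alike, three tall standards (height 5000) on every channel,
and optional planted interferents. The calibration run is generated
noise-free, shift-free and baseline-free so class retention times are exact.
Defaults: 10 samples × 12 channels, 0–40 min at 0.005 min (8001 points),
36 target classes (three per channel, staggered ≥ 1.3 min apart and ≥ 1.5
min from standards), one interferent trailing the first class by 0.12 min at
90% occurrence. One seeded RNG stream drives a batch; identical seeds give
bit-identical batches.

Interferent occurrence is realized exactly — round(occurrence × n_samples)
carrier samples drawn by the RNG — rather than as independent Bernoulli
draws, so the stated occurrence is the realized condition instead of a
random variable with sd ≈ 0.095 at n=10.

What the generator does **not** emulate: asymmetric (tailing/fronting) peak
shapes, nonlinear rt warping within a run, heteroscedastic or multiplicative
detector noise, saturation, and class imbalance across samples. Passing
end-to-end tests therefore demonstrates the correctness of the chain under
its own assumptions (Gaussian shapes, rigid drift, additive noise), not
performance on real air-sample data; on real data the unresolved choices
(which three standards, nonlinear drift) matter and the reported accuracies
do not transfer.

`separable_feature_benchmark` places class means on a 3-D lattice with
spacing `separation` (units of the within-class sd) in Δrt space, with the
channel feature drawn independently of class, so separation 0 is an exact
chance-level null and separation ≥ 10 is linearly separable by construction.

`simulate_coeluted_region` produces one two-Gaussian region (separation 1.5
widths, equal widths, heights 300–900 and 0.4–0.9 of that, noise = smaller
height / SNR) for exercising the goodness-of-fit stopping rule.

## Problem sizes and numerical choices

The package's own studies run at the generator defaults above (10 × 12
traces of 8001 points; a full pipeline run takes seconds on a laptop-class
core). Key tolerances: fitter bounds as listed; amplitude pruning at 0.1% of
region maximum; standard-exclusion radius 0.15 min; recovery scored as a
correctly-classed annotated peak within 2 grid steps of the calibration rt.
Degenerate inputs are handled explicitly: constant regions raise on R²,
all-zero regions return empty results, empty train/test partitions and
single-class training sets raise, and zero-denominator metrics raise unless
converted by flag.

## Known limitations

- Gaussian-only peak shapes; no exponentially modified Gaussian option.
- One rigid shift per channel; no piecewise or correlation-optimized warping.
- The L2-norm selector's scales come from the calibration run's fitted
  maxima; a calibration run with an atypical tallest peak changes scores
  (not usually selections, which the rt term dominates).
- The nearest-rt association rule ignores intensity; a large unknown midway
  between two calibration congeners is attributed to the nearer one.
- mzML support covers chromatogram lists with 32/64-bit float arrays and
  zlib/no compression only; CSV is the canonical format.
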