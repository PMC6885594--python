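# Methods

## Leave-one-out intersubject correlation

The estimator is the Pearson correlation of each subject's regional time
series with the unweighted mean of all other subjects' series for the same
region, repeated over all subjects and regions. The left-out subject is
always excluded from the average; with two subjects the "mean of others" is
simply the other subject. Cells whose own series or leave-one-out mean has
zero variance are flagged invalid (NaN) and excluded from every downstream
summary rather than set to zero — zeros would bias group means toward the
null.

Group summaries average on the Fisher-z scale by default
(`group_mean_isc(..., method="fisher")`: atanh, mean over subjects, tanh
back), the variance-stabilized convention for averaging correlations; raw
averaging is available because display conventions differ between studies
and the choice is not identified by any contract the pipeline must satisfy.
The per-subject "global ISC" is the plain mean over regions.

A note on invariances: ISC is invariant to a *common* affine rescaling of
all subjects and, for a given subject's own row, to rescaling that
subject's series. It is *not* invariant to heterogeneous per-subject
rescaling, because the unweighted leave-one-out mean weights subjects by
their raw scale. Series should therefore arrive variance-normalized or at
least on comparable scales (the synthetic generator standardizes each
series; scanner pipelines typically apply grand-mean scaling).

## Band-pass filtering

BOLD series are restricted to 0.05–0.1 Hz before ISC. The filter is a
4th-order Butterworth band-pass applied forward–backward
(`sosfiltfilt`), preceded by linear detrending and followed by removal of
the tiny residual mean that edge padding reintroduces. Zero-phase
application is essential: a causal filter would delay every subject's
series by a frequency-dependent lag, and although a *common* lag would
cancel in ISC, mixing filtered and unfiltered data or comparing across
filter settings would not. Filtering is applied to the full run before
segment extraction so that edge transients fall outside the analyzed
blocks, not inside 45-sample segments. The filter family and order are
package choices — only the band itself is dictated by the analysis
contract — and both are configurable through `FilterSpec`.

## Surrogate inference and FWER control

The null hypothesis is "no stimulus-locked signal shared across subjects";
it must be rejected per region while controlling the family-wise error
across hundreds of regions. Surrogate datasets are built by
phase-randomizing every subject × ROI series independently: Fourier
amplitudes are kept, phases of non-DC bins are redrawn uniformly (the
Nyquist bin of an even-length series stays real and receives a random
sign), so each surrogate preserves the series' mean, variance, power
spectrum and hence circular autocorrelation, while destroying any
cross-subject temporal alignment. For each of `n_surrogates` iterations
the ISC statistic is recomputed and its maximum across regions recorded;
the rejection threshold is the upper `1 − q` empirical quantile (linear
interpolation between order statistics) of these maxima, and corrected
p-values use add-one counting, `p = (1 + #{max ≥ observed}) / (1 + n)`,
so that no p-value is exactly zero. A region is significant only on
*strict* exceedance of the threshold.

Two statistic/maximization pairings are supported: the default takes the
per-ROI group-mean ISC and maximizes over ROIs; the alternative keeps the
full subjects × ROIs matrix and maximizes over both axes (a stricter
null). The upper-tail reading of the threshold quantile is deliberate:
thresholding at the *lower* q-quantile of the maxima would reject almost
everything and cannot control the family-wise error.

Defaults are `n_surrogates = 10000` and `q = 0.001`; scaled-down runs in
the tests and calibration use 1000 surrogates, which still places the
threshold at the 99.9th percentile of the maxima (interpolated between the
two largest order statistics).

### Implementation

`build_null` never materializes surrogate time series. Because Pearson
correlation ignores the mean (the DC bin) and sums of squares/cross
products are Parseval sums over the one-sided spectrum, the leave-one-out
ISC of a surrogate dataset is computed directly from the randomized
spectra: with per-series spectral variance `vx = Σ w|X|²` (fixed across
surrogates, since amplitudes are preserved) and the subject-sum spectrum
`tot`, the correlation of each subject with the leave-one-out sum
`tot − X` needs only `Σ w Re(X conj(tot))` and `Σ w|tot|²`. The test
suite verifies this spectral route against the time-domain estimator to
rounding error, and the fused kernel against explicit
phase-randomize-then-correlate surrogates fed the same random stream.
Surrogate arithmetic runs in float64 by default; `calibrate_fwer` uses
float32 (the maxima only feed an empirical quantile, where 1e-7 relative
rounding is irrelevant, and halving memory traffic roughly halves the run
time of the calibration). Reproducibility is per seed *and* chunk size,
since chunking determines the order in which random numbers are drawn.

## Contrasts

ISC values are Fisher-z transformed before t statistics and ANOVA by
default (correlations are bounded and their sampling variance depends on
the true value). Per-ROI paired comparisons are corrected across ROIs with
a sign-flipping max-|t| randomization: under the paired null each
subject's difference row is symmetric about zero, so flipping row signs
regenerates the null distribution; the observed |t| is compared to the
upper quantile of the maximum |t| across ROIs. For small groups
(≤ 20 subjects) all 2^n sign patterns can be enumerated, giving exact
permutation p-values `#{max|t| ≥ observed}/2^n` (the identity pattern
guarantees p > 0). The two-way ANOVA treats subject-level ISC values as
independent observations across cells — matching the degrees of freedom
convention of the analysis it mirrors — and reports sequential (Type I)
sums of squares, which coincide with all classical types for the balanced
layouts produced here; a repeated-measures variant is out of scope. If
every observation is identical all F ratios are reported as 0 (all sums of
squares vanish); zero residual variance with non-constant data raises an
error instead.

## Synthetic data generator

The generator emulates the study design the pipeline targets: 26 subjects,
TR = 2 s, two conditions of four clips, each clip a 90-s character segment
followed by a 90-s action segment (45 samples each), with short interludes
excluded from analysis by the schedule. Within a scheduled segment,

    x[s, r, t] = sqrt(a) · g[r, t] + sqrt(1 − a) · ε[s, r, t]

where `g` is one shared standardized signal per ROI per segment and `ε` is
per-subject noise; `a ∈ [0, 1]` is the shared-variance fraction for that
ROI in that condition × segment. Outside any segment the series is pure
noise. Under this model with white noise the population leave-one-out ISC
is `a / sqrt(a + (1 − a)/(n − 1))` (`expected_isc`), the closed form used
to cross-check the estimator (a = 0.3, n = 26 gives 0.524).

Choices worth noting:

- **Shared signal band-limited to 0.05–0.1 Hz** (random Fourier
  coefficients in the band only), so the band-pass stage retains the
  signal while attenuating broadband noise — making the filter
  consequential and testable. Optional convolution with a canonical
  double-gamma hemodynamic response is available (off by default; it
  narrows the spectrum further but changes no contract).
- **AR(1) noise, φ = 0.3 by default** — the minimal model with the
  temporal autocorrelation that the phase-randomization surrogates are
  designed to respect. Noise runs continuously across segment boundaries
  (physiology does not restart at a cut); the shared signal restarts per
  segment.
- **Interludes**: the design's 5-s inter-segment gaps are 2.5 samples at
  TR = 2 s; the default schedule rounds up to 3 whole samples. Interludes
  are excluded by schedule construction, so only the gap's existence — not
  its exact length — matters to any analysis.
- **Standardization**: each final series is z-scored over the run (an
  affine map per series, leaving all correlations untouched), so generated
  sample variances are exactly 1.
- The paper-like preset (`preset_paper_like`) plants `a = 0.5` in
  occipital/temporal ROIs for every condition × segment, in a vmPFC ROI
  only during justified action, and in lOFC/insula ROIs only during
  unjustified action, among 30 labelled ROIs; the end-to-end test recovers
  exactly this dissociation.

What the generator does *not* emulate: voxel-level structure and spatial
smoothness, inter-regional covariance of noise (phases are independent per
ROI; an option to share noise phases within a subject is deliberately not
the default, which yields a stricter null), physiological confounds
(cardiac/respiratory), motion, scanner drifts beyond a linear trend, and
hemodynamic variability across subjects or regions. Passing tests
therefore demonstrate correctness of the estimators and calibration of the
inference *under the stated model*, not robustness to every property of
real BOLD data.

## Calibration

`calibrate_fwer` measures the empirical family-wise error rate of the full
pipeline on global-null data: 2000 independent replicates of
10 subjects × 20 ROIs × 180 timepoints of standardized AR(1) noise
(φ = 0.3), each analyzed with a 1000-surrogate max-statistic null at
q = 0.001. These problem sizes keep the calibration to minutes while the
2000 replicates make the binomial check meaningful (at a true rate of
0.001 the 99% upper bound is 7 rejections). Replicate seeds are spawned
from a single root `SeedSequence`, so the whole calibration is
reproducible from one integer.

## Degenerate inputs and numerical conventions

- Quantiles: linear interpolation between order statistics, everywhere.
- Ties at the threshold: not significant (strict inequality).
- Zero-variance series: invalid ISC cells (NaN), excluded downstream with
  a warning; zero-variance paired differences raise, with a relative
  tolerance of 1e-12 so that constant offsets (whose differences carry
  only rounding noise) are also caught.
- `fisher_z` rejects |r| ≥ 1; internal group averaging uses `arctanh`
  directly so that ISC values of exactly ±1 propagate to ±∞ → tanh
  recovers ±1 rather than erroring.
- Filters require series comfortably longer than the forward–backward
  padding (about 27 samples at the default order) and band edges strictly
  below Nyquist.

## Limitations

Pairwise (subject × subject) ISC matrices, sliding-window dynamic ISC,
voxelwise inference with cluster extent, repeated-measures or
mixed-effects group models, and subject-level covariates are out of scope.
The volumetric ROI extraction path averages voxels within integer atlas
labels and assumes the atlas is already registered to the functional data.
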