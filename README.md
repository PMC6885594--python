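# iscsync

Intersubject correlation (ISC) analysis of regional fMRI BOLD time series:
leave-one-out ISC, phase-randomization surrogate nulls with max-statistic
family-wise error (FWER) control, condition/segment contrasts, and a
synthetic-data generator with the block structure of a naturalistic
movie-viewing experiment.

## Who this is for

Researchers analyzing multi-subject naturalistic-stimulus fMRI (movie
viewing, audio narratives) at the region-of-interest level. When every
subject receives the same time-locked stimulus, regions whose activity is
driven by the stimulus synchronize across subjects; ISC quantifies that
synchrony without needing a task model or a control condition. The package
covers the full inferential pipeline from cleaned per-subject ROI tables to
thresholded region tables, and ships a generator so every stage can be
exercised and calibrated without access to restricted subject data.

## The statistic

For subject *s* and region *r* with time series *x_s,r*, the leave-one-out
ISC is the Pearson correlation with the average of everyone else:

    ISC(s, r) = corr( x_s,r , mean_{j != s} x_j,r )

computed for all subjects and regions, giving a subjects × ROIs matrix.
Significance is assessed non-parametrically: each series is
phase-randomized (Fourier amplitudes kept, phases redrawn uniformly —
preserving mean, variance and autocorrelation), the ISC statistic is
recomputed, and the maximum across ROIs is recorded over `n` surrogates.
Observed values are thresholded at the upper `1 − q` quantile of this
max-statistic null, which controls the probability of *any* false positive
at `q`. Group contrasts (condition A vs B, segment type, region) use
Fisher-z transformed ISC values with paired *t*, sign-flipping max-|t|
randomization across ROIs, or two-way fixed-effects ANOVA.

## Worked example

```bash
python examples/02_surrogate_inference.py
```

simulates 26 subjects viewing two conditions (justified / unjustified
movie violence) of four clips each — every clip a 90-s "character" segment
followed by a 90-s "action" segment at TR = 2 s — band-pass filters to
0.05–0.1 Hz, and tests each condition's action block:

```
justified action: threshold 0.234 (1000 surrogates, q = 0.001)
  significant ROIs (13): occ-calcarine-l, ..., tmp-heschl-r, vmpfc

unjustified action: threshold 0.205 (1000 surrogates, q = 0.001)
  significant ROIs (16): occ-calcarine-l, ..., lofc-l, lofc-r, insula-l, insula-r
```

The threshold is the 99.9th percentile of the surrogate maxima: only
regions beating the most extreme null ISC anywhere in the ROI set are
flagged. The simulated ground truth plants shared signal in sensory
regions for every segment, in vmPFC only during justified action, and in
lOFC/insula only during unjustified action — exactly the sets recovered.
The other examples show the simulation + ISC step itself
(`01_simulate_and_isc.py`), segment/condition contrasts with the global
ISC paired test, sign-flip max-|t| and the two-way ANOVA
(`03_condition_contrasts.py`), and anatomical region tables
(`04_region_table.py`).

## Layout

| Module | Contents |
| --- | --- |
| `iscsync.dataio` | ROI time-series tables, atlas tables, segment schedules, block extraction, volumetric ROI averaging |
| `iscsync.preprocess` | Butterworth band-pass (zero-phase, detrended) |
| `iscsync.isc_core` | leave-one-out ISC, group/global summaries, Fisher z |
| `iscsync.inference` | phase randomization, surrogate max-statistic nulls, FWER thresholds, calibration |
| `iscsync.contrasts` | paired t, sign-flip max-|t|, two-way ANOVA, global ISC comparison |
| `iscsync.report` | anatomical region tables from significance flags |
| `iscsync.synthetic_data` | generative model, block schedules, paper-like preset |

See `docs/methods.md` for the model, parameter choices and limitations.
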