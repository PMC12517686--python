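# Methods

This note documents the models, estimators, parameter choices and known
limitations of `voltsync`. Units are seconds, Hz, cm, micrometers and
radians internally; degrees appear only in reports.

## Data model and time alignment

A session bundles per-cell fluorescence at the imaging rate (2 kHz), one
LFP channel at an integer multiple of it (8 kHz), and behavior resampled to
the imaging rate, all sharing one clock with imaging frame 0 at t = 0.
Sample *i* covers the half-open interval [i/fs, (i+1)/fs); nearest-sample
conversion uses half-up rounding so it is deterministic and monotone. No
clock-drift correction is applied: the acquisition this emulates aligns
streams by hardware triggers, and the generator emits aligned signals by
construction.

## Fluorescence preprocessing and spike detection

The sensor is negative-going, so dF/F is defined as (F₀ − F)/F₀ with
F₀ the ±0.5 s moving average (edge windows shrink rather than pad — this
holds for every moving window in the package). The high-passed residual is
dF/F minus its 5 ms running median.

The spike threshold minimizes an estimate of type-I + type-II error:
candidate amplitudes are the local maxima of the residual, the noise
distribution is the local maxima of the inverted residual, and
err(θ) = P̂(noise ≥ θ) + P̂(candidate < θ) is evaluated on the pooled
amplitude grid with ties resolved to the smallest θ. Two numerical
safeguards matter in practice:

- **Noise-quantile floor.** When a trace contains no true spike
  population the two distributions coincide and err(θ) is flat up to
  sampling noise, so its argmin is arbitrary — occasionally near zero,
  which would pass thousands of noise maxima. The threshold is therefore
  floored at the 99.9th percentile of the noise amplitudes. On traces with
  real spikes this floor sits well below the spike amplitudes and leaves
  detection untouched.
- **SNR gate for subVm clipping.** The subVm (below) interpolates samples
  above a spike-initiation threshold estimated from the mean spike
  waveform. For cells whose detected events do not reach the SNR inclusion
  criterion (SNR > 5) that waveform is noise and the derived threshold can
  fall inside the physiological subVm range, destroying the trace. The
  per-cell driver therefore skips interpolation for sub-criterion cells;
  such cells are excluded by QC from all population analyses anyway.

After thresholding, events smaller than half the **mean** of the top-5%
kept amplitudes are discarded (the mean was chosen over the 95th percentile
for robustness at small event counts). Spike times are refined to
sub-sample precision by 3-point parabolic interpolation. SNR is the mean
spike amplitude over the SD of the residual with [t−2 ms, t+4 ms] excised
around every spike. QC keeps cells with SNR > 5, spike-waveform FWHM
> 0.8 ms (measured on the ±5 ms spike-triggered mean of the residual with
linear interpolation at the half-max crossings) and mean rate > 0.1 Hz,
then greedily drops the lower-SNR member of any pair closer than 70 µm;
a session is analyzable with ≥ 9 surviving cells.

## Behavior

Locomotion is speed > 3 cm/s, immobility < 1 cm/s, per sample, merged into
maximal intervals with no hysteresis (single-sample states are allowed —
the thresholds are stated as pure thresholds). The rate–speed correlation
smooths the spike train with a unit-area Gaussian whose **FWHM** is 250 ms
(σ ≈ 106 ms); the FWHM reading was chosen because kernel "windows" are
conventionally quoted as widths, not SDs.

## Synchrony detection

Counts of all cells' spikes in a 25 ms window are evaluated at every
imaging sample (stride = 1 sample). Each of 500 surrogates displaces every
spike independently by U(−75, +75) ms, clipped to the session; per-sample
surrogate mean and SD define the threshold mean + 4 SD. Contiguous
supra-threshold runs are merged into one event timestamped at the run
midpoint; participants are cells with ≥ 1 spike within ±12.5 ms. A zero-SD
sample still triggers when the count exceeds the surrogate mean.

Two controls: burst removal keeps only spikes whose preceding ISI exceeds
10 ms (a complex-spike-burst convention; the criterion is configurable),
and the theta-cycle shuffle reassigns every spike to a uniformly drawn
cycle while preserving its phase via linear phase-to-time inversion inside
the new cycle (cycles delimited by ascending zero-phase crossings;
non-monotone cycles excluded from the draw).

Detection is conservative by construction: an event's own jittered spikes
inflate the local surrogate mean and SD, so ensembles recruiting few cells
can stay below threshold. At 40% participation across 14 cells roughly
two-thirds of injected events are recovered; at 60% participation recovery
exceeds 90%. The tests validate recovery at the upper end of that range
and calibration (median detected ensemble size) at 40%.

## Cross-correlograms

Time differences (target − reference) are histogrammed in 1 ms bins over
±500 ms. Bin assignment breaks exact boundary ties upward with a 1 ns
nudge: spike times living on the 0.5 ms imaging grid otherwise land
exactly on bin edges and float rounding splits them with a systematic
period, imprinting a comb on the CCG. Grand-average CCGs divide by
(N_ref × N_other_cells); the flat null draws the same number of cells from
other sessions. FWHM is measured at half of (peak − baseline) with the
baseline estimated from |lag| > 400 ms bins and linear interpolation at
the crossings. Single-cell grand CCGs from one 3-minute session are too
noisy for a stable per-cell FWHM (the max bin is dominated by counting
noise), so population-level width statements use the across-cell mean CCG.

Pairwise CCGs require > 100 counts in the window; the peak is the maximum
within ±30 ms (ties: smaller |lag|, then negative); significance jitters
the target train (±75 ms, 1000 iterations) and uses the add-one-corrected
tail fraction; synchronization strength divides the observed peak by the
mean jittered count in the same bin. Under independence the observed peak
is itself a maximum statistic, so strength sits slightly above 1 (≈1 +
2.5/√λ for expected bin count λ); the calibration tests therefore check
p-value uniformity and that observed peaks stay within the jitter-peak
spread, not strength = 1 exactly.

## LFP oscillations

Filters are zero-phase 4th-order Butterworth for the ripple (120–240 Hz)
and theta (4–12 Hz) bands and 2nd-order for the 20 Hz envelope low-pass.
Ripple thresholds (mean + 3.5 / + 7 SD, ≥ 30 ms) use whole-trace envelope
statistics, events included — at physiological ripple rates the inflation
is negligible, but very dense injected ripples (≳0.5 Hz) raise the SD
enough to cost recall, which bounds the event rates used in validation.
The ripple-modulation significance shuffle circularly shifts the whole
train by U(0, T), preserving ISI structure. Phase convention everywhere:
0 rad at the peak of the band-passed oscillation, ±π at the trough;
triggered-LFP spectra zero-pad the 2 s mean trace to 16384 points.

## subVm dynamics

subVm = dF/F − residual with suprathreshold samples linearly interpolated
between the flanking sub-threshold samples (boundary runs extend the
nearest value; an all-suprathreshold trace degenerates to a constant with
a warning). Segments are 1 s with 50% overlap, labeled immobility or
locomotion when the speed criterion holds > 90% of samples. Pairwise
cross-correlation z-scores each segment (positive lag = second cell lags
the first). Coherence within a 1 s segment uses Welch's method with 0.5 s
Hann windows at 50% overlap — a single-window estimate is identically 1,
so at least three half-overlapping windows per segment are needed; this
estimator has a bias floor of roughly 0.3 for independent signals, which
the independence tests account for by comparing against that floor rather
than zero.

## Spatial analysis

36 half-open bins of 2.5 cm on a 90 cm track; spikes and occupancy both
speed-filtered at 3 cm/s; zero-occupancy bins are masked (NaN), never
zero-filled. Selectivity maps bin b to angle 2π(b + 0.5)/36 and takes the
rate-weighted resultant length — the track is treated as circular, the
only consistent way to apply circular variance to a one-way loop. Place
cells: selectivity > 0.25 and peak > 1 Hz, both strict. Tuning similarity
is Spearman over jointly defined bins; the synchrony-vs-tuning relation is
Spearman between locomotion synchronization strengths and similarities
with a 10,000-draw permutation p.

## Synthetic sessions

The generator is statistical, not biophysical; it reproduces the structure
the analysis assumes, with defaults set to the study conditions it
emulates:

- **Behavior**: alternating exponential locomotion (mean 6.5 s) and
  immobility (mean 5.5 s) bouts with 1 s speed ramps, locomotion speed
  ≈ N(8.3, 1.2²) cm/s (never below the 3 cm/s criterion), immobility
  < 1 cm/s; position advances during locomotion and wraps at 90 cm. These
  bout lengths put ~53% of samples above 3 cm/s and ~35% below 1 cm/s.
- **LFP**: theta as a frequency-modulated cosine — 8 Hz in locomotion,
  7 Hz in immobility, low-pass-smoothed transitions — with slow amplitude
  modulation, plus 1/f noise; ripples are 150–200 Hz, 60–100 ms Hann
  bursts injected only in immobility (default 0.04 Hz there) with
  amplitude expressed in multiples (default 8×) of the band-passed
  background SD. Durations of 60–100 ms are typical of CA1 ripples and
  leave the 30 ms duration rule satisfiable at 6× amplitude.
- **Spiking**: lognormal baseline rates (median 3 Hz, σ_log 0.35), a 1.4×
  immobility gain, von Mises theta locking (κ = 0.8 at the theta peak),
  optional complete silencing inside ripples, and a 2 ms refractory.
  Synchronous events arrive as a Poisson process (1 Hz) at theta phases
  drawn von Mises(−30°, κ = 4); each cell joins with probability 0.4 and
  emits one spike within ±12.5 ms. With `anti_correlated_fields`, events
  alternate between two assemblies whose members hold maximally spaced
  fields while the other assembly's fields interleave nearby — making
  strongly synchronous pairs spatially dissimilar.
- **Place fields**: 40% of cells get circular-Gaussian fields (σ = 5 cm)
  scaling the locomotion intensity with unit track average, so tuning does
  not change mean rate.
- **Fluorescence**: per-cell subVm mixes a shared theta source (weight
  0.75) with per-cell theta-band noise correlated across cells as
  exp(−d/400 µm) via a Cholesky factor (weight 0.55), plus a 30 ms
  Gaussian depolarization bump at every synchronous event and slow noise;
  spikes add a biexponential kernel rescaled to exactly the configured
  FWHM (1.2 ms) with amplitude 0.05 dF/F. raw_f = F_base · e^{−t/800 s} ·
  (1 − dF/F_true) + white noise (SD 0.005 · F_base). The bleach constant
  and amplitude keep the spike ≥ 8× the effective dF/F noise through the
  session's end (relative noise grows as fluorescence bleaches).
  Centroids are placed ≥ 70 µm apart in a 1.4 × 1.2 mm field of view so
  QC never rejects for distance by default.

All randomness flows from one mandatory seed through a fixed SeedSequence
spawn order. What the generator does **not** emulate: bursting, lap
structure beyond constant-speed loops, motion artifacts, crosstalk between
ROIs, non-stationary rates, ipsilateral/local ripples, and theta phase
precession — so passing tests demonstrate correctness of the estimators
under the assumed structure, not robustness to those real-data features.

## Pipeline

Stages run as preprocess → behavior → synchrony → correlograms → LFP →
subVm → spatial; each output is a pure function of (input, parameters,
master seed), with per-stage generators spawned from the master seed in a
fixed order, so reruns are byte-identical. Validation problem sizes were
chosen desk-scale: single 180 s sessions of 14–18 cells, 200 surrogate
pairs for null calibration, and a 120 s 10-cell session for end-to-end
determinism. Group-level inferential statistics comparing cohorts are out
of scope; the report carries descriptive medians, IQRs and correlation
coefficients only.
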