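# voltsync

Analysis of **synchronous ensembles of hippocampal CA1 pyramidal cells from
population voltage imaging**, together with a synthetic session generator
that carries a complete ground-truth ledger so every stage of the pipeline
can be validated without access to raw recordings.

Population voltage imaging samples the fluorescence of many CA1 neurons at
2 kHz while an animal explores a track, alongside a contralateral LFP
channel (8 kHz) and behavior tracking. The scientific questions this
package addresses: do many CA1 pyramidal cells fire together within ~25 ms
windows during exploration, how do those synchronous ensembles relate to
ripple (120–240 Hz) and theta (4–12 Hz) oscillations and to the cells'
subthreshold membrane voltage (subVm), and how does pairwise synchrony
relate to place-field organization?

## The statistics at the core

- **Spike extraction from negative-going fluorescence.** Baseline
  F₀(t) is a ±0.5 s moving average; dF/F = (F₀ − F)/F₀ so spikes are
  positive. Spikes are local maxima of the median high-passed dF/F
  (5 ms window) above a threshold θ chosen to minimize
  P(noise ≥ θ) + P(candidate < θ), where the noise amplitude
  distribution comes from local maxima of the *inverted* residual; events
  below half the mean of the top-5% amplitudes are discarded.
  SNR = mean spike amplitude / SD of the spike-excised residual.
- **Population synchrony via jitter surrogates.** Spikes of all cells are
  summed in a 25 ms window sliding sample-by-sample; each of 500 surrogates
  displaces every spike by U(−75, +75) ms. Samples where the observed count
  exceeds the surrogate mean + 4 SD are merged into synchronous events;
  ensemble size is the percentage of analyzable cells with a spike within
  ±12.5 ms of the event.
- **Cross-correlograms.** Grand-average CCGs (1 ms bins, normalized by
  N_ref × N_cells) quantify population co-firing around a reference cell;
  pairwise CCG peaks within ±30 ms are tested against 1000 jitter
  surrogates, with synchronization strength = peak / expected count in the
  same bin (≈1 under independence).
- **Oscillation coupling.** Ripples are detected on the 20 Hz-low-passed
  Hilbert envelope of the 120–240 Hz band (mean + 3.5/7 SD double
  threshold, ≥30 ms). The ripple-modulation index is
  (r_in − r_out)/(r_in + r_out). Phase locking of events or spikes to
  theta uses the amplitude-weighted resultant V_k = A(t_k)·e^{iφ(t_k)};
  strength = |ΣV_k|/Σ|V_k|.
- **subVm coherence.** The subVm is the slow dF/F component with
  suprathreshold excursions interpolated away; pairwise magnitude-squared
  coherence averaged over 4–12 Hz is computed on 1 s half-overlapping,
  state-labeled segments.
- **Place fields.** Occupancy-normalized tuning curves over 36 bins of a
  90 cm track (speed > 3 cm/s); selectivity = 1 − circular variance; place
  cells have selectivity > 0.25 and peak rate > 1 Hz.

## Worked example

```python
import numpy as np
from voltsync import GeneratorConfig, generate_session
from voltsync.preprocess import process_cell, qc_cells
from voltsync.synchrony import detect_population_synchrony
from voltsync.pipeline import match_events

cfg = GeneratorConfig(seed=7)          # 14 cells, 180 s, 40% participation
bundle, truth = generate_session(cfg)

acts = [process_cell(c.cell_id, c.raw_f, c.sampling_rate_hz, bundle.duration_s)
        for c in bundle.cells]
centroids = {c.cell_id: c.centroid_xy for c in bundle.cells}
included, analyzable = qc_cells(acts, centroids, bundle.duration_s)
print(f"cells passing QC: {len(included)}/{len(acts)} (analyzable: {analyzable})")

rates = [a.mean_rate_hz for a in acts if a.cell_id in included]
print(f"median firing rate: {np.median(rates):.2f} Hz")

trains = {a.cell_id: a.spike_times for a in acts if a.cell_id in included}
events = detect_population_synchrony(trains, bundle.duration_s, seed=0)
print(f"synchronous events: {events.n_events} "
      f"({events.n_events / bundle.duration_s:.2f} Hz)")
print(f"median ensemble size: {np.median(events.ensemble_size_pct):.0f}% of cells")

hits, precision, recall = match_events(events.event_times,
                                       truth.true_sync_times, 0.0125)
print(f"recovery of injected ensembles: recall {recall:.2f}, precision {precision:.2f}")
```

prints

```
cells passing QC: 14/14 (analyzable: True)
median firing rate: 3.22 Hz
synchronous events: 265 (1.47 Hz)
median ensemble size: 43% of cells
recovery of injected ensembles: recall 0.64, precision 0.42
```

All 14 synthetic cells pass the inclusion criteria (SNR > 5, waveform FWHM
> 0.8 ms, rate > 0.1 Hz, soma spacing ≥ 70 µm), the median rate sits near
3 Hz, and detected ensembles recruit a median of 43% of the cells. At the
default 40% participation, recall against the generator ledger is ~0.64
because events recruiting few cells stay below the mean + 4 SD surrogate
threshold, and "false positives" are mostly genuine theta-coordinated
coincidences of the background spiking rather than detector noise — raise
`participation_p` to 0.6 and the hit rate climbs above 0.9.

## Command line

```bash
voltsync simulate --seed 1 --out session.h5 --truth truth.json
voltsync run session.h5 --out report/ --seed 0
voltsync score session.h5 --out report/      # synthetic sessions only
voltsync report report/summary.json
```

`run` writes CSV exports per stage (QC table, spikes, state intervals,
synchronous events, pairwise CCGs, ripples, subVm pair table, tuning
curves), a deterministic `summary.json`, and a run log with the version,
seed and parameters.

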