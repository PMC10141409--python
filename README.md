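# ferrotrace

Analysis of single-molecule optical-trapping transmission traces from
plasmonic nanotweezers (double-nanohole apertures), built around one
biophysical question: can the iron-free (apo) and iron-loaded (holo) forms
of the 24-subunit iron-storage protein ferritin be told apart — and the
conversion of one into the other watched live — from nothing but the
transmitted-intensity time series of a trapped molecule?

The package is aimed at single-molecule biophysicists who record long
(minutes) transmission traces of trapped proteins and want a reproducible,
tested pipeline for the standard analysis steps, plus a physics-based
synthetic-trace generator so every stage can be validated without
experimental data.

## The signal model and the two discriminating features

When a protein enters the aperture hot spot the transmitted signal steps up
by *dielectric loading*.  For a small sphere the effect is governed by the
Clausius–Mossotti polarizability

    α = 4π ε₀ r³ (ε̃ₚ − εₘ) / (ε̃ₚ + 2 εₘ),   ε̃ₚ = εₚ + i σ/(ω ε₀),

so a holo-ferritin — about 2 nm larger than apo and carrying a conductive
ferrihydrite core — produces a ~41 % larger fractional step ΔT/T₀.

On top of the step, the trapped molecule writes its dynamics into the
signal: overdamped Brownian motion in the harmonic trap (an
Ornstein–Uhlenbeck process with corner frequency κ/2πγ) and low-frequency
(3–150 Hz) conformational fluctuations of the protein cage.  The flexible
apo cage fluctuates more than the stiff mineral-filled holo cage, so the
**NRMS** (standard deviation over median level of the 1 kHz-filtered
trapped segment) separates the isoforms; combined with ΔT/T₀ it gives a
two-feature classifier.

During Fe²⁺ loading the 3-fold ion channels of the cage unfold and refold,
switching the fluctuation amplitude between an "on" (unfolded, high-RMS)
and an "off" (folded, low-RMS) state with dwell times of seconds; over
~20 minutes mineralization stiffens the cage and the sliding RMS decays
from ~6.8 to ~5.4 mV (at T₀ = 1 V).  The pipeline idealizes the sliding-RMS
series into on/off segments (exhaustive two-cluster split of the log-RMS,
hysteresis, minimum dwell), extracts dwell-time kinetics, and quantifies
the mineralization trend; a ferric (Fe³⁺) control shows neither gating nor
an RMS change.

## Worked example

Generate a 12 s apo-ferritin recording (trap step at 2 s), detect the step,
and summarize the trapped-segment fluctuations:

```sh
$ ferrotrace simulate --preset apo --seed 3 --duration 12 --out apo.h5
wrote 120000 samples to apo.h5

$ ferrotrace detect apo.h5
{
  "baseline": 0.9998141354048979,
  "confidence": "detected",
  "delta_t": 0.0502594779123553,
  "ratio": 0.050268821106436504,
  "t_release": null,
  "t_trap": 2.01
}

$ ferrotrace metrics apo.h5 --t-start 2.6 --t-end 12
{
  "band_fraction_3_150": 0.4631721555246827,
  "median_rms_mv": 6.7736667702826745,
  "nrms": 0.006533781681865419,
  "quartiles": [ 1.0453363155557924, 1.050006560305961, 1.0546796848683853 ]
}
```

Reading the output: the trapping step was located at 2.01 s with a
fractional height ΔT/T₀ ≈ 0.0503 (the apo preset's dielectric-loading
contrast is 0.05; a holo trace yields ≈ 0.0705).  The trapped segment's
median sliding RMS is ≈ 6.8 mV and its NRMS ≈ 0.0065 — the high-fluctuation
signature of the flexible apo cage (the holo preset sits near 0.0059, below
the 0.00624 classifier threshold).  About 46 % of the fluctuation power
lies in the 3–150 Hz conformational band, ~15-fold enriched over a flat
spectrum.

The same operations are available as library calls
(`ferrotrace.trapped_experiment`, `detect_trap_event`, `summarize`,
`segment_states`, `permutation_test`, …), and `ferrotrace run --out DIR`
executes the full study (paired-contrast, iron-loading, gating, NRMS
comparison and ferric-control experiments) and writes a JSON summary, CSV
tables and figures.

## Layout

| module | contents |
| --- | --- |
| `ferrotrace.synthetic` | presets, polarizability, OU trap dynamics, gating process, trace synthesis |
| `ferrotrace.trace` | `Trace` container, HDF5/CSV I/O |
| `ferrotrace.preprocess` | Gaussian low-pass (−3 dB convention), decimation, mode normalization |
| `ferrotrace.events` | change-point detection, T₀ / ΔT / ΔT/T₀ estimation |
| `ferrotrace.metrics` | sliding RMS, NRMS, KDE PDF, quartiles, PSD band fraction |
| `ferrotrace.gating` | on/off segmentation, dwell statistics, mineralization trend, control check |
| `ferrotrace.stats` | permutation test, isoform classifier |
| `ferrotrace.pipeline` | study composition, config validation, report bundle |
| `ferrotrace.cli` | `ferrotrace` command-line tool |

See `docs/methods.md` for the model assumptions, parameter choices,
numerical conventions and known limitations.
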