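# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `ferrotrace`.  It is written for a user who wants
to know what the numbers mean, what the synthetic data do and do not
emulate, and where the genuinely open design choices were made.

## 1. Signal model of the generator

A synthetic recording is

    T(t) = T₀·(1 + δ·o(t)) + o(t)·[c·x(t) + A(t)·ζ(t)] + n(t)

with

* `o(t) ∈ {0,1}` — occupancy; 1 between the trapping time and the release
  time (if any);
* `δ` — fractional dielectric-loading step ΔT/T₀ of the trapped protein;
* `x(t)` — Ornstein–Uhlenbeck position of the particle in the harmonic
  trap, coupled to the signal through the position responsivity `c` (V/m);
* `ζ(t)` — unit-RMS Gaussian conformational noise with power confined to a
  band (3–150 Hz for ferritin), scaled by the amplitude schedule `A(t)`;
* `n(t)` — white Gaussian instrument noise.

The amplitude schedule is `A(t) = a·m(s(t))·d(t)·g(t)` where `a` is the
preset's trapped fluctuation RMS, `m` maps the gating state to a multiplier
(`amp_on = 1`, `amp_off = 0.3` by default), `d(t)` is the mineralization
decay `exp(−max(0, t−t_load)/τ_m)`, and `g(t)` is an optional
piecewise-constant schedule (used only by the ferric control, which steps
its amplitude slightly at the exposure time).

Assumptions worth stating plainly:

* **OU motion uses the exact discrete update** `x[k+1] = e^(−θΔt) x[k] + ξ·
  sqrt((k_B T/κ)(1 − e^(−2θΔt)))`, `θ = κ/γ`, not an Euler step, so the
  stationary variance `k_B T/κ` and lag-1 autocorrelation `e^(−θΔt)` hold
  exactly at any step size and can be pinned by closed-form tests.
* **Conformational noise is flat-spectrum within its band.**  Only the band
  (3–150 Hz) is an empirical input; the spectral shape inside it is a
  declared convention, synthesized in the Fourier domain and normalized to
  RMS 1 (±1e−9).
* **Gating is a two-state Markov renewal process** with i.i.d. exponential
  dwells.  The exponential form is a modelling convention of the generator,
  not an established property of ferritin channel gating.
* **Mineralization is an exponential amplitude decay** with `τ_m = 600 s`,
  chosen so the fluctuation reduction is complete on the ~20-minute
  timescale over which a mineral core forms.  No functional form for this
  decay is established; exponential is the least-structured choice.

## 2. Default parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `T₀` | 1.0 | V | absolute detector scale is arbitrary; all mV figures are read at this scale |
| `fs` | 10 000 | Hz | desk-scale for minutes-long traces; the 1 kHz analysis filter is far below Nyquist |
| `δ` (apo) | 0.05 | – | free contrast scale δ₀ |
| `δ` (holo) | 0.0705 | – | 41 % larger dielectric loading (larger radius + conductive core via the Clausius–Mossotti/Drude polarizability) |
| radius apo / holo | 6 / 7 | nm | ~12 nm outer diameter; holo ~2 nm larger |
| `εₚ` apo / holo, `εₘ` | 2.1 / 2.06, 1.77 | – | protein above water at 852 nm; holo additionally σ = 100 S/m |
| κ | 2×10⁻⁶ | N/m | trap corner κ/2πγ ≈ 3.2 kHz (apo), below Nyquist |
| η, temperature | 8.9×10⁻⁴, 298 | Pa·s, K | water near room temperature |
| `c` | 2×10⁴ | V/m | puts the hydrodynamic term at ~1 mV raw RMS, a minor but nonzero signal contribution |
| conf band | 3–150 | Hz | low-frequency conformational fluctuation band |
| `a` apo | 4.2348 | mV | calibrated (below) |
| `a` holo | 0.794×apo | mV | ratio of the calibrated 5.4/6.8 mV medians |
| instrument noise | 11.721 | mV/sample | calibrated (below) |
| τ_on, τ_off | 3.5 | s | centre of the observed 2–5 s dwell range |
| `amp_off` | 0.3 | – | folded-channel state keeps ~30 % of the conformational amplitude; gives a ~4σ log-RMS contrast for segmentation |
| τ_m | 600 | s | decay essentially complete 22 min into loading |
| control amplitude | 13.225 → 14.330 | mV | calibrated to 14/15 mV medians before/after Fe³⁺ exposure |

## 3. Calibration of the shipped presets

The mV-scale targets (6.8 mV trapped apo, 5.4 mV mineralized endpoint,
14/15 mV ferric control) are *analysis-chain* quantities: medians of the
0.1 s-window sliding RMS of the 1 kHz Gaussian-filtered trace.  The preset
amplitudes were therefore solved through that exact chain (fixed-point
iteration on a 120 s trapped trace; `scratch/calibrate.py` in the source
tree is excluded from the installed package) and frozen as constants:

1. the instrument noise is set so the conformational-free floor
   (OU motion + instrument noise after filtering) reads 5.4 mV;
2. the apo conformational amplitude is set so the trapped apo trace reads
   6.8 mV (the two contributions add in quadrature);
3. the control amplitudes are set the same way for 14 and 15 mV.

A deliberate consequence of (1): the mineralized endpoint *is* the noise
floor.  The decomposition of the 6.8 mV apo signal into a conformational
part (~4.1 mV) and a floor (~5.4 mV) is not empirically constrained —
only the two medians are — and making the decay end at the floor keeps the
22-minute median independent of the on/off state mix inside the
measurement window, which a ±5 % check requires.  The holo preset keeps
the same floor, so its *total* trapped RMS (~6.3 mV) sits between the apo
level and the floor; the apo > holo NRMS ordering is preserved on every
matched seed pair.

## 4. Analysis conventions

* **Gaussian low-pass:** the cutoff is the −3 dB point.  Magnitude response
  `exp(−f²/2σ_f²)` with `σ_f = f_c/√(ln 2)`; zero-phase symmetric kernel,
  reflected edges, so segment boundaries are not shifted.  Filter history
  is appended to trace metadata, never overwritten.
* **Decimation:** zero-phase FIR (Hamming, 20·factor+1 taps) with cutoff at
  0.8× the new Nyquist, then subsampling.
* **Mode normalization / PDF:** Gaussian KDE with Silverman's bandwidth on
  a 4096-point grid spanning `[min−3h, max+3h]`, evaluated by binning plus
  Gaussian smoothing (deterministic, O(n)).  The PDF metric and the mode
  divisor share this code path, so the PDF argmax equals the normalization
  divisor by construction.
* **Change points:** binary segmentation on the least-squares statistic
  with penalty `2σ̂² log n`, `σ̂` from the MAD of first differences
  (robust to the steps themselves).  For noise-free input the penalty
  degenerates to a floating-point floor so that any real step is accepted
  while cancellation noise is not.  The trapping step is the change point
  with the largest level jump; levels are medians (robust to asymmetric
  conformational fluctuations); a 0.5 s post-trap settling window is
  excluded; release is the first later step returning within 3 pre-trap
  noise SDs of T₀.  For long traces, detection runs on a 100 Hz decimated
  copy (5 ms resolution, ≪ the 50 ms accuracy target).
* **Sliding RMS:** per-window RMS of per-window mean-subtracted samples
  (cumulative-sum implementation), default 0.1 s window / 0.05 s hop —
  ≥ 20 points per 2–5 s dwell.  Reported in mV for a trace in volts.
* **NRMS:** standard deviation over median of the filtered trapped
  segment.  Distributions are built from 1 s sub-traces.  The definition
  (std/median, per-second aggregation) is a declared convention; its
  scale invariance is what makes values comparable across apertures.
* **PSD band fraction:** Welch, Hann, ~4/f_lo-second power-of-two
  segments, 50 % overlap; in-band power over power above f_lo/2.
* **Segmentation:** exhaustive two-cluster split of the log-RMS (exact 1-D
  2-means); threshold at the cluster-mean midpoint; hysteresis band
  ±0.25× the separation; runs shorter than `min_dwell = 0.5 s` merged into
  neighbours; the higher-RMS cluster is "on" (unfolded channels).
  *Unimodality guard:* a 2-means split of a unimodal Gaussian already
  yields separation ≈ 2.65× the pooled within-cluster SD (half-normal
  means ±√(2/π)σ, within-SD √(1−2/π)σ), so the single-state criterion is
  set at 3.2× — above that baseline, below the ~4× of genuine gating at
  the shipped contrast.  For control recordings with a known exposure
  time, segmentation covers the exposure period so the slow pre/post
  level drift is not mistaken for gating.
* **Dwell statistics:** first and last segments are censored (their true
  extent is unobserved) and excluded; the arithmetic mean of the remaining
  dwells is the exponential-model MLE.
* **Permutation test:** two-sided, difference of means, seeded.  Exact
  enumeration whenever `C(n, n_a)` does not exceed the permutation budget
  (hence always exact for total n ≤ 10 at default settings); otherwise
  Monte Carlo with the add-one estimator `p = (1+k)/(B+1)`, so p is never
  0 and never below 1/(B+1).
* **Classifier:** holo iff NRMS < 6.24×10⁻³ and ΔT/T₀ > 0.06025 (both
  strict); apo iff both reversed; anything else — including a feature
  exactly on a threshold — is undetermined.  Thresholds are midpoints
  between the preset population means, overridable.
* **Seeding:** every stage derives its streams from one master seed via
  `SeedSequence([master, stage_key])`; child streams inside the generator
  are derived statelessly, so the same configuration is bit-identical on
  rerun.

## 5. Problem sizes of the shipped study

The full study (pipeline defaults, also used by `scripts/acceptance.py`)
uses 20 paired 60 s contrast traces, one 1420 s iron-loading trace
(loading begins 60 s after trapping; the late window starts 22 min after
that), one 130 s gating trace (120 s loading phase, no mineralization
decay, since dwell kinetics concern the phase before mineralization
completes), 50 one-second NRMS segments per isoform with 10⁵ permutations,
and one 1320 s ferric control — all at 10 kHz.  These sizes keep a full
run around half a minute on one CPU while leaving every estimate's
sampling error well inside its check's tolerance, with one exception noted
below.

## 6. What the generator does and does not emulate

Emulated: baseline/step/release structure, band-limited conformational
noise, trap hydrodynamics with size-dependent drag, two-state amplitude
gating with exponential dwells, slow mineralization decay, white
instrument noise, and ground-truth channels (occupancy, state, boundaries,
position) for every trace.

Not emulated: the electromagnetic response of the aperture (the step is a
phenomenological δ, not a field calculation), laser heating, Fe²⁺/Fe³⁺
chemistry beyond the two-state phenomenology, 1/f drifts, multi-protein
co-trapping, non-exponential dwell distributions, and any coupling between
the OU motion and the conformational state.  Passing tests therefore
demonstrate that the *analysis chain* recovers what the *model* puts in;
they do not validate the model against real recordings.

## 7. Known limitations

* **Dwell-time dead time.**  Any segmentation with a minimum dwell `d`
  misses exponential dwells shorter than `d`; by memorylessness the
  recovered dwells then average at least `τ + d`, and merging across
  missed events raises this further (≈ 4.9 s at τ = 3.5 s, d = 0.5 s,
  against a 2–5 s plausibility window).  With only ~12 uncensored dwells
  in a 120 s trace the recovered mean also carries a ~1 s standard error.
  The recovered mean dwell should be read as an upper-biased estimate of
  τ; unbiased estimates require either the generator's ground-truth
  boundaries (as the estimator-consistency tests use) or much longer
  recordings.
* The unimodality guard is calibrated for Gaussian-like log-RMS window
  noise; heavy-tailed RMS series could cross the 3.2× criterion without
  genuine two-state gating.
* The classifier thresholds are preset-population midpoints at T₀ = 1 V;
  real instruments need their own feature calibration.
* CSV I/O quantizes at 9 significant digits (relative error < 1e−8);
  HDF5 is lossless.
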