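# Methods

This note documents the models, conventions and numerical choices behind
`gammappi`, and what the synthetic generator does and does not establish.

## Session model and conventions

Time is in seconds with t = 0 at recording start; event onsets are stimulus
onsets, and the 100-ms prepulse lead is onset-to-onset. Signals are in μV,
spectral densities in μV²/Hz, ERSP values in dB re the pre-stimulus baseline.
The default timeline follows the behavioural protocol: 15-min baseline,
pretreatment injection, 25-min gap, NMDAr-antagonist injection, then a 60-min
(MK-801-like) or 30-min (ketamine-like) primary period. The 10-min
acclimatisation that precedes acquisition is not represented (no data are
analysed from it). Channel combination always happens after per-channel
analysis — block band powers and ERSP maps are averaged across channels,
never raw signals.

## Ongoing power

* Epochs: contiguous, non-overlapping 2-s segments; trailing partial epoch
  discarded.
* Welch settings inside an epoch (not dictated by the source description,
  declared here): Hann window, 1-s segments, 50 % overlap → ~1 Hz
  resolution, density scaling (Parseval: integral ≈ variance). The estimate
  is restricted to 1–200 Hz for analysis; the full grid is available for
  variance checks.
* "Band power" is the **mean** spectral value over bins whose centre lies in
  [30, 80] Hz inclusive, not the integral; the percent-of-baseline
  normalisation makes downstream results convention-independent.
* 1-min blocks average the ~30 epoch values whose start times fall in the
  block; empty blocks are missing (NaN), never zero.
* The baseline is the mean over pre-pretreatment blocks; baseline blocks
  therefore average to exactly 100 %.
* A 50 Hz IIR notch (Q = 30) is available but OFF by default — the modelled
  acquisition hardware removes mains noise, and the generator's default line
  amplitude is zero.

## Evoked power

* Epochs −400…+600 ms around each prepulse onset; only prepulse+pulse trials
  after the NMDAr-antagonist injection enter the evoked analysis. Trials
  whose window leaves the recording are dropped and logged.
* Morlet grid: 180 linearly spaced frequencies, 20–200 Hz. The cycle count
  rises from 3 to 10; the schedule is **linear in frequency** by default
  (n(f) = 3 + 7·(f−20)/180), with a geometric (EEGLAB-style multiplicative)
  schedule as a config option — the source description states only
  "increasing from 3 to 10".
* Wavelet σ_t = n/(2πf); kernels are truncated at ±half support = ±n/(2f).
  Epochs are not padded: cells within half a support of an epoch edge are
  masked invalid. At 20 Hz/3 cycles the mask reaches ±75 ms, so the
  −300…0 ms baseline and 0–100 ms score windows stay valid everywhere.
* Output maps are sampled every 2 ms. Power is trial-averaged first, then
  converted to dB against the per-frequency baseline mean (grand-average
  ERSP convention); per-trial dB averaging is deliberately not the default.
* The **evoked gamma score** averages *power* over 30–80 Hz × 0–100 ms,
  converts to dB, and subtracts the identically averaged −300…0 ms baseline
  (i.e. 10·log10 of a ratio of window-mean powers). The alternative —
  averaging per-cell dB values — is exposed as `db_average=True`. The two
  agree on uniform maps; the power-domain form matches the description of
  averaging power values before expressing them in dB, and is well behaved
  for bursts that occupy part of the window.

## %PPI

%PPI = 100·(1 − mean(prepulse+pulse)/mean(pulse-alone)) from per-session
trial means over the primary period (per-block %PPI is an option). The
measure is invariant to a common rescaling of amplitudes, so per-subject
accelerometer gain cancels. Facilitation yields negative values.

## Repeated-measures statistics

Classical one-way within-subject decomposition; F = MS_treatment/MS_error on
(k−1, (k−1)(n−1)) df, upper-tail p. No sphericity correction by default
(matching Prism-era reporting); Greenhouse–Geisser is available. Incomplete
tables are refused with an instruction to remove affected subjects listwise,
mirroring the study's handling. Planned comparisons are two-sided paired
t-tests, Bonferroni-adjusted by the size of the pre-registered family only
(each pretreatment+antagonist vs vehicle+antagonist, plus vehicle+vehicle vs
vehicle+antagonist) — never all pairwise. Zero-variance difference vectors
are reported as p = 1 (zero mean difference) or limiting p = 0 rather than
NaN. The baseline-drift check is the same ANOVA with session order as the
factor, its df taken from the table actually supplied.

## Synthetic generator: the stated world

No recordings are deposited for this kind of study, so the generator defines
the test world explicitly:

* **Background**: pink noise with one-sided PSD a²/f (a = 10 μV at 1 Hz,
  flattened below 1 Hz), drawn independently per channel.
* **Ongoing gamma**: 30–80 Hz Butterworth-filtered noise, RMS 55 μV, shared
  across channels; after the antagonist injection its amplitude is scaled by
  `ongoing_gain` with a 30-s exponential onset. The in-band gamma:background
  power ratio (~30:1) is deliberately larger than physiological so that the
  percent-of-baseline readout recovers `100·gain²` within the stated ±10 %
  despite the background's dilution and the onset transient.
* **Evoked bursts**: one Gabor atom per prepulse, centred 50 ms after onset,
  σ_t = 25 ms (so ≥90 % of burst energy lies in the scored 0–100 ms window),
  per-trial centre frequency uniform in 40–70 Hz, peak amplitude
  210 μV × `evoked_gain`.
* **Behaviour**: pulse-alone startle ~ log-normal (σ_log = 0.3) with median
  `startle_mean` × subject scale; prepulse+pulse = the same draw ×
  (1 − ppi_true/100).
* **Schedule**: trials throughout the session; ITI uniform on [10, 20] s
  (the source states only the 15-s mean); exactly two trials of each kind
  per block of four, randomly ordered (pseudorandom, non-alternating).
* **Cohort**: complete within-subject design; per-subject multiplicative
  random effects (log-SD 0.4 on startle, 0.2 on signal amplitude) applied
  identically across that subject's sessions; condition order randomised per
  subject. Child seeds derive from (master seed, subject, condition,
  component), so adding a condition never perturbs existing sessions.

**Presets.** No measured effect magnitudes are available for this paradigm,
so preset values encode the ordinal pattern only: antagonist ongoing_gain 1.8 (~300 % of
baseline), evoked_gain 0.3, ppi_true 10 vs vehicle 60; clozapine
(ongoing 1.05, evoked 0.9, ppi 35) is the sole rescue; haloperidol also
raises startle_mean to 160. Because the evoked readout is a
burst-to-background ratio, conditions that suppress ongoing gamma would
mechanically score higher for the same absolute burst — contradicting the
reported pharmacology, in which ongoing-gamma normalisation does not
restore evoked power. The no-rescue antipsychotic presets therefore carry a
background correction (evoked_gain 0.3·√(1.10/3.24) ≈ 0.18) that holds their
*measured* evoked level at the antagonist condition's.

**What a green test establishes.** The generator emulates the statistical
structure the analysis assumes — 1/f background, band-limited ongoing gamma,
stimulus-locked bursts, log-normal startle, subject random effects. It does
not emulate artifacts, non-stationary arousal, drug pharmacokinetics beyond
a single exponential, electrode differences between hemispheres beyond
independent noise, or habituation. Passing tests therefore validate the
pipeline's correctness and sensitivity under the stated world, not the
biological effect sizes.

## Scaled-down execution

The test and acceptance suites run a proportionally shrunk session
(240/180/480 s at 500 Hz instead of 900/1500/3600 s at 2 kHz) and a single
combined 8-condition cohort instead of separate MK-801-like and
ketamine-like cohorts, purely for runtime; all analysis windows derive from
event times, so nothing changes in kind. The end-to-end ordinal check uses
n = 12 subjects; at the protocol's n = 6 the clozapine PPI rescue is only a
trend under these presets (seen in the README example).

## Known limitations

* EDF support is read-only and minimal (equal-rate continuous int16
  signals); proprietary acquisition formats are out of scope.
* No artifact rejection beyond validation of finite samples; a corrupted
  channel must be excluded by the caller before channel averaging.
* The ERSP omits inter-trial phase coherence and evoked/induced separation;
  the startle-pulse-locked response is not analysed.
* Statistics cover the one-way within-subject design only (no mixed models,
  no two-way designs, no non-parametrics).
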