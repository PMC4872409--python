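# gammappi

Concurrent ECoG gamma-oscillation and prepulse-inhibition (PPI) analysis for
NMDA-receptor-antagonist pharmacology studies in rodents.

## The scientific problem

Acute NMDAr antagonists (MK-801, ketamine) reproduce three robust readouts of
glutamatergic hypofunction in rats carrying extradural cortical electrodes
inside a startle chamber:

* **elevated ongoing gamma power** — spontaneous 30–80 Hz activity rises after
  the injection;
* **reduced prepulse-evoked gamma** — the transient gamma burst locked to the
  78 dB acoustic prepulse shrinks;
* **a sensorimotor-gating deficit** — %PPI of the acoustic startle collapses.

Antipsychotic pretreatments dissociate these readouts: the clinical compounds
suppress the ongoing-gamma elevation, but only clozapine restores evoked gamma
and (partially) PPI. `gammappi` re-implements the full analysis workflow as a
tested, reusable library + CLI, together with a synthetic session generator so
the complete pipeline runs with no animal data.

## The measures

With signal $x(t)$ (μV, 2 kHz, two hemispheric channels analysed separately
and averaged at the derived-measure stage):

* **Ongoing gamma.** 2-s epochs → Welch density $P(f)$ over 1–200 Hz (Hann,
  1-s segments, 50 % overlap) → gamma band power $\bar P_{30-80}$ (mean over
  band bins) → 1-min block means → percent of the pre-injection baseline mean
  (baseline ≡ 100 %); outcome = mean % over the post-injection primary period.
* **Evoked gamma.** Epochs −400…+600 ms around each post-injection prepulse
  ($t=0$ at prepulse onset) → complex Morlet decomposition on 180 linear
  frequencies 20–200 Hz with cycles rising 3→10 → trial-averaged power
  $\bar S(f,t)$ → ERSP $10\log_{10}[\bar S(f,t)/B(f)]$ with per-frequency
  baseline $B(f)$ over −300…0 ms → evoked score
  $10\log_{10}\frac{\langle \bar S\rangle_{30-80\,\mathrm{Hz},\,0-100\,\mathrm{ms}}}{\langle \bar S\rangle_{30-80\,\mathrm{Hz},\,-300-0\,\mathrm{ms}}}$ (dB).
* **%PPI.** $100\,(1 - \overline{A}_{pp}/\overline{A}_{pa})$ from primary-period
  trial-mean startle amplitudes (prepulse+pulse vs pulse-alone).
* **Statistics.** One-way repeated-measures ANOVA per outcome
  ($F = MS_{treat}/MS_{err}$ on $(k-1,(k-1)(n-1))$ df, complete tables only)
  with Bonferroni-adjusted planned paired comparisons
  ($p_{adj} = \min(1, m\,p)$ over the pre-registered family), plus a
  baseline-drift RM-ANOVA across session order.

## Worked example

```python
import gammappi as g

cfg = g.StudyConfig(n_subjects=6, seed=1)   # desk-scale design, all presets
bundle = g.run_study(cfg, keep_maps=False)
res = bundle.anovas["ppi_pct"]
print(f"PPI: F({res.df1},{res.df2}) = {res.F:.2f}, p = {res.p:.3g}")
print(bundle.comparisons["ppi_pct"].round(4).to_string(index=False))
```

prints

```
PPI: F(7,35) = 19.26, p = 2.81e-10
           cond_a        cond_b  mean_diff       t  p_raw  p_adjusted  significant
  vehicle_vehicle vehicle_nmdar    43.6138 23.2227 0.0000      0.0000         True
  clozapine_nmdar vehicle_nmdar    17.8624  3.9844 0.0105      0.0734        False
    dserine_nmdar vehicle_nmdar    -3.5510 -0.8126 0.4534      1.0000        False
haloperidol_nmdar vehicle_nmdar    -8.9258 -2.1692 0.0822      0.5756        False
   ly379268_nmdar vehicle_nmdar    -0.9609 -0.2647 0.8018      1.0000        False
       nfps_nmdar vehicle_nmdar    -9.2054 -1.6340 0.1632      1.0000        False
 olanzapine_nmdar vehicle_nmdar    -3.6035 -0.5437 0.6100      1.0000        False
```

Reading this: the omnibus treatment effect on %PPI is overwhelming; the
antagonist deficit (vehicle_vehicle vs vehicle_nmdar, ~44 points) is highly
significant, the clozapine rescue (~18 points) is a trend at this scaled-down
n = 6, and no other pretreatment moves PPI — at n = 12 subjects (used in the
acceptance suite) the clozapine comparison is reliably significant. The same
bundle holds `evoked_db` and `ongoing_pct` tables showing the clozapine-only
evoked rescue and the broad suppression of the ongoing elevation.

## Command line

```bash
gammappi simulate --design scaled --n-subjects 6 --seed 1 --out sessions/
gammappi analyze  --in sessions/ --out outcomes.csv
gammappi stats    --in outcomes.csv --outcome ppi_pct --out stats/
gammappi run-study --seed 1 --out results/   # composite, config optional
gammappi render   --seed 1 --out figures/    # ERSP + ongoing heatmaps
```

## File formats

* **native-hdf5** — `<name>.h5` (datasets: `signal` (channels × samples, μV);
  attrs: `fs`, `start_time`, `channel_ids`, `subject_id`, `condition_id`,
  `session_order`) with tidy sidecars `<name>.events.csv`
  (`onset_s, kind, level_db, duration_ms`) and `<name>.trials.csv`
  (`index, kind, pulse_onset_s, startle_amp`). Lossless round trip.
* **csv-pair** — plain-text signal matrix plus the same sidecars.
* **edf** — European Data Format, read-only, same sidecar convention.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
runs the package's main computation from scratch — generates the preset
synthetic cohort at the given seed, computes all four outcome measures per
session and the repeated-measures statistics — and writes the results JSON.
Model details, generator assumptions and numerical choices are documented in
`docs/methods.md`.
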