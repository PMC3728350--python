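# circabehave

Analysis pipeline for circadian rhythms of locomotor activity and
immobility-defined sleep in laboratory rodents, built for studies that
track wheel-running (counts per 3-min bin) and video-scored immobility
(per-second immobile-area fractions) across light:dark (LD), constant
darkness (DD) and skeleton-photoperiod conditions.

It is aimed at chronobiologists who need the standard actogram metric
panel — free-running period, rhythm power, nocturnality, activity
amount, alpha, onset precision, bout fragmentation — plus photic
phase-shift estimation, immobility-defined sleep statistics, and the
group-level tests that populate a genotype-by-age results table. A
matched synthetic-data generator produces actograms and mobility traces
with known ground truth, so every analysis stage can be verified
without animal data.

## Core methods

**Chi-square periodogram.** For a candidate period of *p* bins the
record is folded into *K* complete cycles and

&nbsp;&nbsp;&nbsp;&nbsp;*Q*<sub>p</sub> = *n′* · Σ<sub>h</sub> *K*<sub>h</sub>(*M*<sub>h</sub> − *M̄*)² / Σ<sub>i</sub>(*x*<sub>i</sub> − *M̄*)²

with *M*<sub>h</sub> the *p* column means, *K*<sub>h</sub> the
replicates per column and *n′* = *Kp* the points examined. Under white
noise *Q*<sub>p</sub> ~ χ²(*p* − 1), which gives the *P* < 0.05
significance line; tau is the candidate with the largest significant
*Q*<sub>p</sub> and rhythm power is reported as
%V = *Q*<sub>p</sub>(tau) · 100/*n′* (100 for a perfectly repeating
waveform).

**Actogram metrics.** Nocturnality = per-day percentage of counts in
the dark window, averaged. Alpha = longest circularly contiguous run of
average-waveform bins above the waveform mean. Precision = mean
absolute deviation of daily activity onsets from their best-fit
regression line. Fragmentation = bouts/day, where a bout tolerates
sub-threshold gaps under 21 min and must last at least 21 min.

**Phase shifts.** Aschoff type-II style: regression lines through the
onsets of the 7 days before and 7 days after a light pulse (skipping
post-pulse transient cycles), both extrapolated to the first post-pulse
day; positive differences are delays.

**Immobility-defined sleep.** Sleep = runs of ≥ 95% immobility lasting
≥ 40 s, aggregated in ZT-aligned 1-min bins; totals split at ZT 12
(day = ZT 0–12, night = ZT 12–24), bouts = runs of minutes each holding
≥ 40 s of sleep, with 90/95/97% threshold-sensitivity deltas.

## Worked example

```python
import circabehave as cb

params = cb.ActivitySimParams(tau_hours=23.62, alpha_minutes=612.9,
                              nocturnality_target=None)
rec = cb.simulate_activity(params, cb.LightSchedule.dd(), n_days=10)
res = cb.chi_square_periodogram(rec, 20.0, 28.0)
print(res.tau_hours, res.power_pct)
```

prints `23.6 99.10213687085529`: the periodogram recovers the
generating 23.62-h free-running period at the nearest 0.05-h scan step
(one 3-min bin), and the rhythm power of the noiseless record is
99.1%V, just under the theoretical ceiling of 100 because the period is
not an exact bin multiple.

The `analysis/` scripts run the same pipeline over a three-group
synthetic cohort (a gene-dose gradient in rhythm robustness, 8 animals
per group) and write per-animal metric tables and group statistics
under `results/`:

```
python analysis/01_simulate_cohorts.py
python analysis/02_circadian_metrics.py
python analysis/03_photic_responses.py
python analysis/04_sleep_analysis.py
python analysis/05_group_statistics.py
```

A `circabehave` command-line interface (`validate`, `convert`,
`periodogram`, `metrics`, `phaseshift`, `sleep`, `simulate`, `compare`)
wraps the same functions for plain-text CSV records.

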