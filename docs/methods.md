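# Methods

## Time conventions

All analysis is anchored to Zeitgeber time: ZT 0 = lights-on, ZT 12 =
lights-off under 12:12 LD. Days are half-open intervals
[ZT 0, ZT 0 + 24 h); bin indices are 0-based. Under constant darkness
the ZT frame of the last LD cycle is retained as "projected" ZT, with
a declared 12-h subjective night (default ZT 12–24); this is how
day-folding and waveform averaging are anchored in DD, where no
external cycle defines a phase reference. Under the skeleton
photoperiod (1:11:1:11 LDLD) the two 1-h pulses are placed at ZT 0–1
and ZT 12–13, framing the prior light phase, and the declared
subjective night is ZT 12–24 (the evening pulse marks dusk); the
pulses' exact placement within the frame is a convention, since only
the night window enters any statistic.

Missing activity bins are carried as NaN sentinels and excluded from
every mean; they are never zero-filled, because zero-filling inflates
nocturnality and deflates periodogram power. Gap bins also reduce the
number of points examined, n′, in the periodogram.

## Chi-square periodogram

For each candidate period of p bins (integer bin multiples spanning
20–28 h by default, i.e. 0.05-h steps at 3-min bins), the first
K = ⌊N/p⌋ complete cycles are folded into a K × p layout and

    Qp = n′ · Σ_h K_h (M_h − M̄)² / Σ_i (x_i − M̄)²

where M_h are the p column means, K_h the number of valid samples
behind each (K everywhere in a gap-free record), M̄ the grand mean and
n′ the valid points examined. The numerator is the between-columns sum
of squares of the folded one-way layout, so Qp is n′ times the
fraction of variance explained by the folded waveform: it reaches n′
for a perfectly repeating signal and is asymptotically χ²(p − 1) under
white noise, which supplies the P < 0.05 significance line. The
incomplete final cycle is dropped rather than partially weighted,
keeping that null exact. Tau is the candidate with the largest Qp
among those above the line, ties resolved toward the smaller period
for determinism; rhythm power is %V = Qp(tau)·100/n′ with n′ taken at
the peak candidate. A zero-variance record returns a defined
arrhythmic result (Qp ≡ 0, tau absent) rather than failing. Scan
range, step and alpha are all arguments.

The statistic is a ratio, so it is invariant to positive rescaling of
the counts; Monte-Carlo calibration on Poisson white noise (checked in
the test suite at 200 records) gives a per-candidate exceedance of the
significance line close to the nominal 5% — slightly conservative, as
is typical for the finite-K χ² approximation.

## Actogram metrics

**Average waveform** — per-bin mean and SEM across days (within
animal), gaps excluded.

**Nocturnality** — per-day percentage of counts in the dark (or
declared subjective-night) window, averaged across days; zero-activity
days are excluded and flagged rather than contributing 0/0.

**Activity amount** — total counts divided by valid recording hours.

**Alpha** — the waveform mean is the threshold; alpha is the longest
circularly contiguous run of bins strictly above it, i.e. the
onset-to-offset span of the consolidated active phase. This matches
the chronobiological reading of alpha as active-phase length; a
`mode="total"` variant reports total suprathreshold time instead.
Because the threshold is the mean, alpha is invariant both to adding a
constant to every bin and to positive rescaling. A flat waveform
yields alpha 0 ("arrhythmic").

**Onset detection** — commercial actogram software does not publish
its onset rule, so the rule here is explicit and config-exposed: bin B
is a day's onset if counts stayed below threshold for the preceding 4 h
with at most one violating bin, and at least 50% of the bins in the
following 1 h (including B) are above threshold, where threshold = 0.2
× the day's mean positive-bin count. These defaults were chosen for
robustness on the synthetic generator across jitter levels and are
documented so users can match other software.

An optional *sub-bin refinement* locates the onset within the onset
bin by comparing its partial count (or the partial count spilling into
the preceding bin) with the local fully-active rate. The refinement
assumes a locally constant rate, which makes it exact on noiseless
square-wave records; it is off by default for metric panels and on by
default inside phase-shift estimation, where bin quantization would
otherwise floor a shift that is not a bin multiple.

**Precision** — onsets are unwrapped across the 24-h boundary
(nearest-cycle rule), a least-squares line of onset minute against day
index is fit, and precision is the mean absolute residual in minutes,
reported non-negative. Published tables sometimes print this quantity
with a negative sign; that appears to be a software convention, and
the magnitude is the interpretable quantity. At least three onsets are
required.

**Fragmentation** — a bout opens at a bin above the count threshold
(default 0, appropriate for sparse wheel data and configurable),
tolerates sub-threshold gaps shorter than 21 min, closes before any
≥ 21-min gap, and must last ≥ 21 min; fragmentation is mean bouts/day.
Bouts are attributed to the day of their onset.

## Photic responses

**Phase shift** — estimated Aschoff type-II style from activity
onsets: a regression line through the 7 onsets ending on the pulse day
(the pulse at CT 16 falls after that day's onset) and one through 7
onsets starting after 2 transient cycles, both extrapolated to the
first post-pulse day; the difference is the shift, positive for
delays. The 7/7/2 windows follow common practice for this assay and
are all arguments, as is the minimum of 5 usable onsets per side. For
simulation, CT 12 is activity onset and the pulse is timed 4·(tau/24) h
later — standard circadian-time scaling.

**Skeleton-photoperiod entrainment** — percentage of activity in the
declared subjective night, computed exactly as nocturnality.

## Immobility-defined sleep

Sleep is scored on the raw per-second immobility trace: maximal runs
of samples at or above the immobility threshold (default 95% of the
animal's area) lasting at least 40 s are sleep; shorter runs are wake.
The scored flag is then aggregated on a ZT-aligned 1-min grid (partial
first/last minutes dropped). The 40-s minimum applies twice, by
design: once to the per-second episode, and once as the ≥ 40 s/min
rule that defines minute-level bouts — these are two distinct rules of
the scoring protocol, not a redundancy.

Totals sum sleep minutes in ZT 0–12 (day) and ZT 12–24 (night),
averaged across full days. A bout is a maximal run of minutes each
holding ≥ 40 s of sleep; bouts spanning ZT 12 (or ZT 0) are split at
the boundary so that day/night attribution is exclusive and
day + night sleep equals total sleep exactly. Bout counts and mean
durations are computed per day and averaged across days. Bout-duration
distributions bin daytime durations in 30-min classes normalized to
the daytime bout count, with a finer-interval variant for sub-30-min
structure. Threshold sensitivity re-scores the trace at 90/95/97%
immobility and reports each metric's percent change from the 95%
baseline (undefined, and flagged, where the baseline is zero). Total
sleep is non-increasing in both the threshold and the minimum episode
length — nested exceedance sets — and the test suite asserts both.

## Group statistics

Metrics that pass Shapiro–Wilk normality (per group, n ≥ 3) and Levene
equal-variance checks at α = 0.05 are compared by one-way ANOVA
(F, dof (k−1, N−k)); failures route to the Kruskal–Wallis ANOVA on
ranks (tie-corrected H, χ²(k−1)). After a significant omnibus test,
all pairwise comparisons use t statistics on the pooled within-group
variance with Bonferroni-adjusted p = min(1, m·p). Calling the
post-hoc routine with a non-significant omnibus p raises unless
explicitly forced. Omnibus and gate alphas are arguments. Two-way
repeated-measures designs and Dunn's method are deliberately out of
scope — they are routine and better served by dedicated statistics
software, for which the pipeline's long-format CSV output is intended.

## Synthetic-data generators

The generators are mechanistic-phenomenological rather than
oscillator-based: the analysis metrics are phenomenological, so ground
truth must be expressible in the same vocabulary (a phase line, an
active-phase length, a dark-phase share, bout processes). They do not
model gene-dose or age trajectories, light-intensity dependence, or
EEG-level sleep structure.

**Activity** — each day's onset follows the phase line (locked to
lights-off under LD/skeleton; advancing by (tau − 24)·60 min/day in
DD from a projected ZT 12 start), optionally jittered N(0, σ²). A
constant-rate active phase of length alpha is laid at 1-min
resolution with fractional partial minutes, interrupted by a Poisson
gap process; light masking multiplies lights-on activity by
(1 − suppression); under LD/skeleton the day's counts are reallocated
so the dark-phase share equals the nocturnality target exactly;
minutes are then summed into bins and optionally Poisson-sampled.
Defaults describe a robust young-adult wild-type wheel-runner: tau
23.62 h, alpha 612.9 min, nocturnality 97.5%, and an active-phase rate
of 2900 counts/hr, which averages to ~1240 rev/hr over the day —
values typical of published wild-type panels. Noiseless output is a
deterministic function of the parameters; all stochastic components
flow from one seeded generator per call.

**Pulse experiments** — the onset line shifts by the imposed amount
from the cycle after the pulse, optionally ramping linearly over k
transient cycles; everything else is the DD generator.

**Mobility** — each 12-h window is filled with alternating wake/sleep
bouts: sleep durations are shifted exponentials (the 40-s minimum plus
an exponential tail preserving the window's mean bout length), wake
durations exponential with the mean that yields the window's target
sleep fraction. Windows begin with wake so scored runs never merge
across window boundaries, and boundary-truncated sleep remnants
shorter than the minimum are relabeled wake — together these make the
scored bout table equal the returned ground-truth table exactly at
zero jitter. Immobility is a two-level signal (defaults 0.98 asleep /
0.20 awake, bracketing the 95% threshold) plus clipped Gaussian
jitter. Default fractions (0.55 day, 0.25 night) and bout means
(10 min day, 5 min night) describe a strongly diurnal-sleeping mouse.

**What passing recovery tests show** — the generators produce
consolidated square-wave-like activity and two-state immobility;
real records have graded onsets, within-bout rate structure, and
intermediate immobility values. Recovery of generator parameters
therefore validates the estimators' correctness and conventions, not
their robustness to every feature of real data; the jitter, gap,
masking and noise knobs exist to probe robustness explicitly.

## Numerical choices and known limitations

- Candidate periods are integer bin multiples; tau resolution is one
  scan step (0.05 h at 3-min bins). Periodogram ties break toward the
  smaller period.
- With few cycles of i.i.d. onset jitter, the *realized* period of a
  record (the slope of its actual onset line) differs from the nominal
  generator tau by the jitter's sampling error — at σ = 20 min over 10
  days, by up to ~0.08 h. Recovery tests therefore assert the estimate
  falls within one scan step of the nominal-to-realized bracket; no
  estimator can recover the nominal value more tightly than the data
  determine it.
- The problem sizes used throughout (10-day records, 16-day pulse
  assays, 2–3-day sleep traces, 8 animals per synthetic group, 200-
  record null calibrations) match the designs this pipeline targets
  and keep any run to seconds.
- Resampling to coarser bins requires the factor to divide the record
  length (always true for day-aligned records); groups containing a
  gap become gaps.
- Sub-bin onset refinement assumes a locally constant active-phase
  rate; on noisy data it adds sub-bin variance and is therefore off by
  default outside phase-shift estimation.
- The %V normalization uses n′ at the peak candidate; periodogram
  software differs on this point (some normalize against the
  significance line), so cross-software power values may differ by a
  scale factor even when tau agrees.
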