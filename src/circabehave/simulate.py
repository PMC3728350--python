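"""Synthetic actograms and mobility traces with known ground truth.

The generators are mechanistic-phenomenological: a daily phase line
(onset advancing by ``(tau - 24) * 60`` min/day in constant darkness,
or locked to lights-off under entrainment) carries a consolidated
active phase of length alpha, with optional onset jitter, within-bout
gaps, Poisson count noise, light masking and an exact dark-phase
activity share.  Mobility traces alternate exponential sleep/wake
bouts per 12-h window.  Ground truth is expressed in the same
vocabulary as the analysis metrics (tau, alpha, nocturnality, onsets,
bout tables) so every statistic has a recoverable target.

Default parameter values describe a healthy young adult wild-type
mouse on a running wheel: free-running period 23.62 h, active phase
612.9 min, 97.5% of activity in the dark, and an active-phase wheel
rate matching ~1240 revolutions/hr averaged over the day.

All randomness flows from a single seeded generator per simulation
call; with ``noise='NONE'`` and zero jitter the output is a
deterministic function of the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .schedule import LightSchedule, Regime
from .timeseries import ActivityRecord, MobilityTrace, MINUTES_PER_DAY


@dataclass
class ActivitySimParams:
    """Generative parameters for a synthetic wheel-running actogram."""

    tau_hours: float = 23.62
    alpha_minutes: float = 612.9
    mean_rate: float = 2900.0  # counts/hr within the active phase
    nocturnality_target: float | None = 0.975  # dark-phase share (LD/skeleton)
    onset_jitter_sd_min: float = 0.0
    gap_rate_per_hr: float = 0.0  # expected gaps per active-phase hour
    mean_gap_min: float = 10.0
    noise: str = "NONE"  # NONE | POISSON
    masking_light_suppression: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (20.0 <= self.tau_hours <= 28.0):
            raise ValidationError("tau_hours must lie in [20, 28]")
        if not (0.0 < self.alpha_minutes <= MINUTES_PER_DAY):
            raise ValidationError("alpha_minutes must lie in (0, 1440]")
        if self.mean_rate <= 0:
            raise ValidationError("mean_rate must be positive")
        if self.nocturnality_target is not None and not (0.0 < self.nocturnality_target <= 1.0):
            raise ValidationError("nocturnality_target must lie in (0, 1]")
        if self.noise not in ("NONE", "POISSON"):
            raise ValidationError("noise must be NONE or POISSON")


@dataclass
class SleepSimParams:
    """Generative parameters for a synthetic two-state mobility trace."""

    day_sleep_fraction: float = 0.55
    night_sleep_fraction: float = 0.25
    mean_bout_day_min: float = 10.0
    mean_bout_night_min: float = 5.0
    immobility_in_sleep: float = 0.98
    immobility_in_wake: float = 0.2
    jitter_sd: float = 0.0
    min_bout_seconds: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("day_sleep_fraction", "night_sleep_fraction",
                     "immobility_in_sleep", "immobility_in_wake"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        for frac, mean in ((self.day_sleep_fraction, self.mean_bout_day_min),
                           (self.night_sleep_fraction, self.mean_bout_night_min)):
            if 0.0 < frac and mean * 60.0 <= self.min_bout_seconds:
                raise ValidationError(
                    "mean sleep bout must exceed the minimum episode length"
                )


# ----------------------------------------------------------------------
# activity
# ----------------------------------------------------------------------

def _add_interval(arr: np.ndarray, a: float, b: float, rate: float) -> None:
    """Add ``rate`` per minute over continuous interval [a, b) with partial edges."""
    a = max(a, 0.0)
    b = min(b, float(arr.size))
    if b <= a:
        return
    first = int(np.floor(a))
    last = int(np.ceil(b))
    for m in range(first, last):
        lo = max(a, m)
        hi = min(b, m + 1)
        if hi > lo:
            arr[m] += rate * (hi - lo)


def _daily_onsets(params: ActivitySimParams, schedule: LightSchedule,
                  n_days: int, rng: np.random.Generator) -> np.ndarray:
    if schedule.regime is Regime.DD:
        base = 720.0
        drift = (params.tau_hours - 24.0) * 60.0
        onsets = base + drift * np.arange(n_days)
    else:
        onsets = np.full(n_days, schedule.night_window[0] % 24.0 * 60.0)
    if params.onset_jitter_sd_min > 0:
        onsets = onsets + rng.normal(0.0, params.onset_jitter_sd_min, n_days)
    return onsets


def _lay_activity(
    onsets_min: np.ndarray,
    params: ActivitySimParams,
    schedule: LightSchedule,
    n_days: int,
    bin_minutes: float,
    rng: np.random.Generator,
) -> ActivityRecord:
    total_min = int(n_days * MINUTES_PER_DAY)
    per_min = np.zeros(total_min)
    rate = params.mean_rate / 60.0  # counts per minute
    for d, onset in enumerate(onsets_min):
        a = d * MINUTES_PER_DAY + onset
        _add_interval(per_min, a, a + params.alpha_minutes, rate)
        if params.gap_rate_per_hr > 0:
            n_gaps = rng.poisson(params.gap_rate_per_hr * params.alpha_minutes / 60.0)
            for _ in range(n_gaps):
                g0 = a + rng.uniform(0.0, params.alpha_minutes)
                glen = rng.exponential(params.mean_gap_min)
                _add_interval(per_min, g0, min(g0 + glen, a + params.alpha_minutes), -rate)
    np.clip(per_min, 0.0, None, out=per_min)

    minute_of_day = np.arange(total_min) % MINUTES_PER_DAY
    if params.masking_light_suppression > 0 and schedule.lights_on:
        light = np.zeros(total_min, dtype=bool)
        for s, e in schedule.lights_on:
            light |= (minute_of_day >= s * 60.0) & (minute_of_day < e * 60.0)
        per_min[light] *= 1.0 - params.masking_light_suppression

    if params.nocturnality_target is not None and schedule.regime is not Regime.DD:
        t = params.nocturnality_target
        a, b = schedule.night_window
        dark = ((minute_of_day / 60.0 - a) % 24.0) < (b - a)
        for d in range(n_days):
            sl = slice(int(d * MINUTES_PER_DAY), int((d + 1) * MINUTES_PER_DAY))
            dm, lm = dark[sl], ~dark[sl]
            dsum = per_min[sl][dm].sum()
            lsum = per_min[sl][lm].sum()
            if dsum == 0:
                continue
            want_light = dsum * (1.0 - t) / t
            seg = per_min[sl]
            if lsum > 0:
                seg[lm] *= want_light / lsum
            elif want_light > 0:
                seg[lm] = want_light / lm.sum()

    if abs(bin_minutes - round(bin_minutes)) > 1e-9 or bin_minutes < 1:
        raise ValidationError("simulator bins must be whole minutes")
    n_bins = int(round(total_min / bin_minutes))
    counts = per_min.reshape(n_bins, int(round(bin_minutes))).sum(axis=1)
    if params.noise == "POISSON":
        counts = rng.poisson(counts).astype(float)
    return ActivityRecord(counts, bin_minutes, 0.0, schedule)


def simulate_activity(
    params: ActivitySimParams,
    schedule: LightSchedule,
    n_days: int = 10,
    bin_minutes: float = 3.0,
) -> ActivityRecord:
    """Simulate a binned wheel-running record under the given schedule.

    Under DD the daily onset follows the free-running phase line from a
    projected ZT 12 start; under LD/skeleton it locks to lights-off
    (night-window start) and, when ``nocturnality_target`` is set, each
    day's counts are reallocated so the dark-phase share equals the
    target exactly.
    """
    if params.nocturnality_target is not None and schedule.regime is Regime.DD:
        # target is undefined without a dark/night window: silently ignored in DD
        pass
    rng = np.random.default_rng(params.seed)
    onsets = _daily_onsets(params, schedule, n_days, rng)
    return _lay_activity(onsets, params, schedule, n_days, bin_minutes, rng)


def simulate_pulse_experiment(
    params: ActivitySimParams,
    schedule: LightSchedule,
    pulse_day: int,
    imposed_delay_min: float,
    n_days: int = 16,
    transient_days: int = 0,
    bin_minutes: float = 3.0,
) -> ActivityRecord:
    """Simulate a DD light-pulse assay with an imposed phase shift.

    Onsets follow the free-running line up to ``pulse_day``; from the
    next cycle they shift by ``imposed_delay_min`` (positive = delay),
    optionally ramping linearly over ``transient_days`` cycles.  The
    pulse itself is timed at CT 16, i.e. 4 * (tau / 24) h after the
    onset of ``pulse_day`` (standard circadian-time scaling); only its
    phase consequence is modeled.
    """
    if schedule.regime is not Regime.DD:
        raise ValidationError("pulse experiment requires a DD schedule")
    if not (0 <= pulse_day < n_days):
        raise ValidationError("pulse_day outside the simulated record")
    rng = np.random.default_rng(params.seed)
    onsets = _daily_onsets(params, schedule, n_days, rng)
    d = np.arange(n_days, dtype=float)
    frac = np.clip((d - pulse_day) / (transient_days + 1.0), 0.0, 1.0)
    onsets = onsets + imposed_delay_min * frac
    return _lay_activity(onsets, params, schedule, n_days, bin_minutes, rng)


# ----------------------------------------------------------------------
# mobility
# ----------------------------------------------------------------------

@dataclass
class MobilitySim:
    trace: MobilityTrace
    sleep_intervals: pd.DataFrame  # ground truth: start_sec, end_sec (half-open)


def simulate_mobility(
    params: SleepSimParams,
    schedule: LightSchedule | None = None,
    n_days: int = 3,
) -> MobilitySim:
    """Simulate a per-second immobility trace with a known sleep bout table.

    Each 12-h window (ZT 0-12 day, ZT 12-24 night) is filled with
    alternating wake/sleep bouts: sleep durations are shifted
    exponentials (minimum episode length plus an exponential tail with
    the window's mean), wake durations exponential with the mean that
    yields the window's target sleep fraction.  Windows begin with a
    wake bout so scored runs never merge across window boundaries;
    boundary-truncated sleep remnants shorter than the minimum episode
    are relabeled wake.  Immobility is ``immobility_in_sleep`` /
    ``immobility_in_wake`` plus clipped Gaussian jitter.
    """
    schedule = schedule or LightSchedule.ld()
    rng = np.random.default_rng(params.seed)
    half = 12 * 3600
    total = int(n_days * 24 * 3600)
    sleeping = np.zeros(total, dtype=bool)
    intervals: list[tuple[int, int]] = []
    min_s = int(round(params.min_bout_seconds))

    for w in range(2 * n_days):
        w0, w1 = w * half, (w + 1) * half
        is_day = (w % 2) == 0
        frac = params.day_sleep_fraction if is_day else params.night_sleep_fraction
        mean_sleep = (params.mean_bout_day_min if is_day else params.mean_bout_night_min) * 60.0
        if frac <= 0.0:
            continue
        if frac >= 1.0:
            sleeping[w0:w1] = True
            intervals.append((w0, w1))
            continue
        mean_wake = mean_sleep * (1.0 - frac) / frac
        t = w0
        state_sleep = False  # start with wake: no merging across boundaries
        while t < w1:
            if state_sleep:
                dur = min_s + int(round(rng.exponential(mean_sleep - min_s)))
                end = min(t + dur, w1)
                if end - t >= min_s:
                    sleeping[t:end] = True
                    intervals.append((t, end))
                t = end
            else:
                t += max(1, int(round(rng.exponential(mean_wake))))
            state_sleep = not state_sleep

    imm = np.where(sleeping, params.immobility_in_sleep, params.immobility_in_wake)
    if params.jitter_sd > 0:
        imm = imm + rng.normal(0.0, params.jitter_sd, total)
    imm = np.clip(imm, 0.0, 1.0)
    trace = MobilityTrace(imm, 1.0, 0.0, schedule)
    truth = pd.DataFrame(intervals, columns=["start_sec", "end_sec"])
    return MobilitySim(trace=trace, sleep_intervals=truth)
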