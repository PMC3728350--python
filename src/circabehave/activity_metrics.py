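"""Scalar circadian metrics from a binned activity record.

Covers the standard actogram-derived panel: daily average waveform,
nocturnality (% of activity in the dark), activity amount (rev/hr),
alpha (active-phase duration above the waveform mean), activity-onset
detection, onset precision about a best-fit regression line, and bout
fragmentation (bouts/day with a max-gap rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .schedule import Regime
from .timeseries import ActivityRecord, DayMatrix, MINUTES_PER_DAY, fold_days


@dataclass
class DailyWaveform:
    """Per-bin mean and SEM across days; spans exactly 24 h."""

    mean: np.ndarray
    sem: np.ndarray | None
    bin_minutes: float


@dataclass
class ActivityMetrics:
    """The Table-style metric panel for one animal/record."""

    nocturnality_pct: float | None
    activity_rev_per_hr: float
    alpha_minutes: float
    precision_minutes: float | None
    fragmentation_bouts_per_day: float
    tau_hours: float | None = None
    power_pct: float | None = None


def average_waveform(day_matrix: DayMatrix) -> DailyWaveform:
    """Column-wise mean and SEM across days (gaps excluded from both)."""
    v = day_matrix.values
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(v, axis=0)
    if day_matrix.n_days < 2:
        return DailyWaveform(mean, None, day_matrix.bin_minutes)
    n = np.isfinite(v).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(v, axis=0, ddof=1)
        sem = np.where(n >= 2, sd / np.sqrt(n), np.nan)
    return DailyWaveform(mean, sem, day_matrix.bin_minutes)


def _window_activity_pct(record: ActivityRecord, per_day: bool = False):
    """Per-day % of counts falling in the schedule's night window, averaged."""
    dm = fold_days(record)
    mask = record.schedule.night_mask(record.bin_minutes)
    pcts = []
    for row in dm.values:
        tot = np.nansum(row)
        if tot <= 0:
            pcts.append(np.nan)  # zero-activity day: excluded, flagged as NaN
        else:
            pcts.append(100.0 * np.nansum(row[mask]) / tot)
    pcts = np.asarray(pcts)
    if per_day:
        return pcts
    if not np.isfinite(pcts).any():
        raise InsufficientDataError("no day with positive total activity")
    return float(np.nanmean(pcts))


def nocturnality(record: ActivityRecord, per_day: bool = False):
    """Average percentage of activity conducted during the dark phase.

    Defined for LD and skeleton schedules (a dark or subjective-night
    window must exist).  Per-day percentages are averaged; days with
    zero total activity are excluded.
    """
    if record.schedule.regime is Regime.DD:
        raise ValidationError("nocturnality requires an LD or skeleton schedule")
    return _window_activity_pct(record, per_day=per_day)


def activity_rate(record: ActivityRecord) -> float:
    """Mean counts per hour over the record; gap bins contribute no time."""
    finite = np.isfinite(record.counts)
    hours = finite.sum() * record.bin_minutes / 60.0
    if hours == 0:
        raise InsufficientDataError("record contains no valid bins")
    return float(np.nansum(record.counts) / hours)


def alpha_duration(waveform: DailyWaveform, mode: str = "span") -> float:
    """Active-phase duration: time the average waveform exceeds its mean.

    ``mode='span'`` (default) returns the longest circularly-contiguous
    run of bins strictly above the mean, i.e. the onset-to-offset span
    of the consolidated active phase.  ``mode='total'`` returns total
    suprathreshold time instead.  A waveform with no bin above its mean
    is arrhythmic: alpha = 0.
    """
    m = waveform.mean
    thr = np.nanmean(m)
    above = np.where(np.isfinite(m), m > thr, False)
    if not above.any():
        return 0.0
    if mode == "total":
        return float(above.sum() * waveform.bin_minutes)
    if mode != "span":
        raise ValidationError(f"unknown alpha mode {mode!r}")
    if above.all():
        return float(above.size * waveform.bin_minutes)
    # longest circular run: double the array and scan runs
    doubled = np.concatenate([above, above])
    best = run = 0
    for flag in doubled:
        run = run + 1 if flag else 0
        best = max(best, run)
    best = min(best, above.size)
    return float(best * waveform.bin_minutes)


@dataclass
class OnsetParams:
    """Activity-onset detection rule (all knobs config-exposed).

    A bin B is the day's onset if (a) counts stayed below threshold for
    ``quiet_hours`` before B with at most ``max_violations`` violating
    bins, and (b) at least ``active_frac`` of bins in the following
    ``active_window_h`` (including B) exceed threshold.  Threshold is
    ``threshold_frac`` times the day's mean positive-bin count.
    """

    threshold_frac: float = 0.2
    quiet_hours: float = 4.0
    active_window_h: float = 1.0
    active_frac: float = 0.5
    max_violations: int = 1


def detect_onsets(
    day_matrix: DayMatrix,
    params: OnsetParams | None = None,
    subbin: bool = False,
) -> np.ndarray:
    """Per-day activity-onset minutes (ZT minutes); NaN where no bin qualifies.

    With ``subbin=True`` the onset is refined within the onset bin by
    comparing its count with the local fully-active rate (assumes a
    locally constant rate; exact on noiseless square-wave data).
    """
    params = params or OnsetParams()
    flat = day_matrix.values.ravel()
    bpd = day_matrix.values.shape[1]
    bin_min = day_matrix.bin_minutes
    qbins = int(round(params.quiet_hours * 60.0 / bin_min))
    abins = max(1, int(round(params.active_window_h * 60.0 / bin_min)))

    onsets = np.full(day_matrix.n_days, np.nan)
    for d in range(day_matrix.n_days):
        day = day_matrix.values[d]
        positive = day[np.isfinite(day) & (day > 0)]
        if positive.size == 0:
            continue
        thr = params.threshold_frac * positive.mean()
        for b in range(bpd):
            g = d * bpd + b  # global bin index
            if not (np.isfinite(flat[g]) and flat[g] > thr):
                continue
            prev = flat[max(0, g - qbins) : g]
            violations = int(np.sum(np.isfinite(prev) & (prev >= thr)))
            if violations > params.max_violations:
                continue
            window = flat[g : min(flat.size, g + abins)]
            frac = np.mean(np.isfinite(window) & (window > thr))
            if frac < params.active_frac:
                continue
            onset = b * bin_min
            if subbin:
                # fractional-bin refinement: the partial count in (or just
                # before) the onset bin, relative to the local fully-active
                # rate, locates the onset within the bin; exact on noiseless
                # square-wave data.
                follow = flat[g + 1 : min(flat.size, g + 1 + abins)]
                ref = follow[np.isfinite(follow) & (follow > thr)]
                if ref.size:
                    c_ref = ref.mean()
                    prev_val = flat[g - 1] if g > 0 else np.nan
                    if np.isfinite(prev_val) and 0.0 < prev_val <= thr:
                        onset -= bin_min * float(np.clip(prev_val / c_ref, 0.0, 1.0))
                    else:
                        onset += bin_min * (1.0 - float(np.clip(flat[g] / c_ref, 0.0, 1.0)))
            onsets[d] = onset
            break
    return onsets


def unwrap_onsets(onsets: np.ndarray) -> np.ndarray:
    """Unwrap onset minutes across the 24-h boundary (nearest-cycle rule)."""
    out = onsets.astype(float).copy()
    last = np.nan
    for i, o in enumerate(out):
        if not np.isfinite(o):
            continue
        if np.isfinite(last):
            k = np.round((last - o) / MINUTES_PER_DAY)
            out[i] = o + k * MINUTES_PER_DAY
        last = out[i]
    return out


def onset_precision(onsets: np.ndarray, days: np.ndarray | None = None) -> float:
    """Mean absolute deviation of onsets from their best-fit line, in minutes.

    Onsets are unwrapped across the 24-h boundary before fitting a
    least-squares line of onset minute against day index.  Requires at
    least three non-absent onsets.
    """
    onsets = np.asarray(onsets, dtype=float)
    if days is None:
        days = np.arange(onsets.size)
    days = np.asarray(days, dtype=float)
    unwrapped = unwrap_onsets(onsets)
    ok = np.isfinite(unwrapped)
    if ok.sum() < 3:
        raise InsufficientDataError("insufficient onsets: need >= 3")
    coef = np.polyfit(days[ok], unwrapped[ok], 1)
    resid = unwrapped[ok] - np.polyval(coef, days[ok])
    return float(np.mean(np.abs(resid)))


def activity_bouts(
    record: ActivityRecord,
    count_threshold: float = 0.0,
    max_gap_minutes: float = 21.0,
    min_bout_minutes: float = 21.0,
) -> pd.DataFrame:
    """Detect activity bouts with a max-gap merge rule.

    A bout opens at a bin with counts above ``count_threshold``,
    tolerates sub-threshold gaps shorter than ``max_gap_minutes``, and
    closes at the last suprathreshold bin before a gap of at least
    ``max_gap_minutes``.  Bouts shorter than ``min_bout_minutes`` are
    discarded.  Returns one row per bout: day, start/end minute within
    the day (end exclusive), duration and total counts.
    """
    bin_min = record.bin_minutes
    for name, v in (("max_gap_minutes", max_gap_minutes), ("min_bout_minutes", min_bout_minutes)):
        if abs(v / bin_min - round(v / bin_min)) > 1e-9:
            raise ValidationError(f"{name} must be a multiple of the bin width")
    dm = fold_days(record)
    flat = dm.values.ravel()
    bpd = dm.values.shape[1]
    active = np.isfinite(flat) & (flat > count_threshold)
    gap_bins = int(round(max_gap_minutes / bin_min))

    bouts = []
    start = None
    last_active = None
    for i, a in enumerate(active):
        if a:
            if start is None:
                start = i
            elif (i - last_active - 1) >= gap_bins:
                bouts.append((start, last_active))
                start = i
            last_active = i
    if start is not None:
        bouts.append((start, last_active))

    rows = []
    for s, e in bouts:
        duration = (e - s + 1) * bin_min
        if duration < min_bout_minutes:
            continue
        rows.append(
            {
                "day": int(dm.day0 + s // bpd),
                "start_minute": float((s % bpd) * bin_min),
                "end_minute": float((s % bpd) * bin_min + duration),
                "duration_minutes": float(duration),
                "total_counts": float(np.nansum(flat[s : e + 1])),
            }
        )
    return pd.DataFrame(rows, columns=["day", "start_minute", "end_minute", "duration_minutes", "total_counts"])


def fragmentation(record: ActivityRecord, **bout_kwargs) -> float:
    """Mean number of activity bouts per day."""
    dm = fold_days(record)
    table = activity_bouts(record, **bout_kwargs)
    return len(table) / dm.n_days
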