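"""Immobility-defined sleep scoring and derived sleep statistics.

Sleep is inferred from video-tracked immobility: an episode of samples
with at least 95% of the animal's area immobile, sustained for at least
40 s, is scored as sleep (thresholds validated against EEG in the
source tracking literature).  Scored sleep is then aggregated on a
ZT-aligned 1-min grid; day (ZT 0-12) and night (ZT 12-24) totals, bout
counts (a bout = consecutive minutes each holding >= 40 s of sleep),
mean bout durations, bout-duration distributions and threshold
sensitivity are derived from that grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .timeseries import MobilityTrace

MIN_PER_DAY = 1440
MIN_PER_HALF = 720


@dataclass
class SleepSeries:
    """Per-sample sleep flag plus the ZT-aligned per-minute sleep seconds."""

    flag: np.ndarray  # per-sample bool
    sleep_seconds: np.ndarray  # per full minute, in [0, 60]
    minute0: int  # ZT minute index of sleep_seconds[0]
    sample_seconds: float
    threshold_used: float
    min_episode_seconds: float
    schedule: object = None

    @property
    def n_full_days(self) -> int:
        lead = (-self.minute0) % MIN_PER_DAY
        return (self.sleep_seconds.size - lead) // MIN_PER_DAY


@dataclass
class SleepMetrics:
    """Across-day averages of the daily sleep panel."""

    day_sleep_min: float
    night_sleep_min: float
    day_bouts: float = np.nan
    night_bouts: float = np.nan
    day_mean_bout_min: float = np.nan
    night_mean_bout_min: float = np.nan

    def as_dict(self) -> dict:
        return {
            "day_sleep_min": self.day_sleep_min,
            "night_sleep_min": self.night_sleep_min,
            "day_bouts": self.day_bouts,
            "night_bouts": self.night_bouts,
            "day_mean_bout_min": self.day_mean_bout_min,
            "night_mean_bout_min": self.night_mean_bout_min,
        }


def score_sleep(
    trace: MobilityTrace,
    threshold: float = 0.95,
    min_seconds: float = 40.0,
) -> SleepSeries:
    """Score sleep as sustained immobility and bin it on the ZT minute grid.

    Maximal runs of samples with immobility >= ``threshold`` lasting at
    least ``min_seconds`` are sleep; shorter runs are wake.  Runs are
    evaluated on the raw per-sample flag before minute-binning; partial
    first/last minutes are dropped from the minute grid.
    """
    imm = trace.immobility
    ss = trace.sample_seconds
    if ss > 1.0 + 1e-9:
        raise ValidationError("trace must be sampled at >= 1 Hz")
    if abs(60.0 / ss - round(60.0 / ss)) > 1e-9:
        raise ValidationError("sample interval must divide 60 s")
    min_samples = int(np.ceil(min_seconds / ss - 1e-9))

    immobile = imm >= threshold
    flag = np.zeros_like(immobile)
    i = 0
    n = immobile.size
    while i < n:
        if immobile[i]:
            j = i
            while j < n and immobile[j]:
                j += 1
            if (j - i) >= min_samples:
                flag[i:j] = True
            i = j
        else:
            i += 1

    # ZT-aligned minute grid
    per_min = int(round(60.0 / ss))
    start_sample = int(round(trace.start_time * 3600.0 / ss))
    lead = (-start_sample) % per_min
    usable = (flag.size - lead) // per_min
    if usable < 1:
        raise InsufficientDataError("trace shorter than one full minute")
    grid = flag[lead : lead + usable * per_min].reshape(usable, per_min)
    sleep_seconds = grid.sum(axis=1) * ss
    minute0 = (start_sample + lead) // per_min
    return SleepSeries(
        flag=flag,
        sleep_seconds=sleep_seconds,
        minute0=minute0,
        sample_seconds=ss,
        threshold_used=threshold,
        min_episode_seconds=min_seconds,
        schedule=trace.schedule,
    )


def _full_day_grid(series: SleepSeries) -> tuple[np.ndarray, int]:
    """Reshape per-minute sleep seconds into full ZT days (day0 index returned)."""
    lead = (-series.minute0) % MIN_PER_DAY
    n_days = (series.sleep_seconds.size - lead) // MIN_PER_DAY
    if n_days < 1:
        raise InsufficientDataError("series spans less than one full day")
    grid = series.sleep_seconds[lead : lead + n_days * MIN_PER_DAY].reshape(n_days, MIN_PER_DAY)
    day0 = (series.minute0 + lead) // MIN_PER_DAY
    return grid, day0


def sleep_totals(series: SleepSeries) -> SleepMetrics:
    """Day (ZT 0-12) and night (ZT 12-24) sleep minutes, averaged across days."""
    grid, _ = _full_day_grid(series)
    day_min = grid[:, :MIN_PER_HALF].sum(axis=1) / 60.0
    night_min = grid[:, MIN_PER_HALF:].sum(axis=1) / 60.0
    return SleepMetrics(float(day_min.mean()), float(night_min.mean()))


def sleep_bouts(series: SleepSeries, min_sec_per_bin: float = 40.0) -> pd.DataFrame:
    """Minute-resolution sleep bouts: runs of minutes each with >= 40 s sleep.

    Bouts spanning the ZT 12 (or ZT 0) boundary are split so that
    day/night attribution is exclusive.  Returns one row per bout:
    day, window ('day'/'night'), start minute of day, duration (min).
    """
    grid, day0 = _full_day_grid(series)
    flat = (grid.ravel() >= min_sec_per_bin)
    rows = []
    n = flat.size
    i = 0
    while i < n:
        if not flat[i]:
            i += 1
            continue
        j = i
        while j < n and flat[j]:
            j += 1
        # split the run [i, j) at every 720-min boundary
        s = i
        while s < j:
            boundary = ((s // MIN_PER_HALF) + 1) * MIN_PER_HALF
            e = min(j, boundary)
            day = s // MIN_PER_DAY
            mod = s % MIN_PER_DAY
            rows.append(
                {
                    "day": int(day0 + day),
                    "window": "day" if mod < MIN_PER_HALF else "night",
                    "start_minute": float(mod),
                    "duration_minutes": float(e - s),
                }
            )
            s = e
        i = j
    return pd.DataFrame(rows, columns=["day", "window", "start_minute", "duration_minutes"])


def sleep_metrics(series: SleepSeries, min_sec_per_bin: float = 40.0) -> SleepMetrics:
    """Full panel: totals plus bout counts and mean durations, per-day averaged."""
    totals = sleep_totals(series)
    bouts = sleep_bouts(series, min_sec_per_bin)
    grid, day0 = _full_day_grid(series)
    days = day0 + np.arange(grid.shape[0])

    counts = {"day": [], "night": []}
    durs = {"day": [], "night": []}
    for d in days:
        for w in ("day", "night"):
            sel = bouts[(bouts["day"] == d) & (bouts["window"] == w)]
            counts[w].append(len(sel))
            if len(sel):
                durs[w].append(sel["duration_minutes"].mean())
    return SleepMetrics(
        day_sleep_min=totals.day_sleep_min,
        night_sleep_min=totals.night_sleep_min,
        day_bouts=float(np.mean(counts["day"])),
        night_bouts=float(np.mean(counts["night"])),
        day_mean_bout_min=float(np.mean(durs["day"])) if durs["day"] else np.nan,
        night_mean_bout_min=float(np.mean(durs["night"])) if durs["night"] else np.nan,
    )


def bout_duration_distribution(
    bouts: pd.DataFrame,
    interval_minutes: float = 30.0,
    window: str = "day",
    max_minutes: float | None = None,
) -> pd.DataFrame:
    """Histogram of bout durations normalized to the total bout count.

    Durations in the chosen window are binned into classes of
    ``interval_minutes`` and each class is divided by the total number
    of bouts in that window.  ``max_minutes`` restricts the histogram
    (e.g. a fine-resolution view of bouts under 30 min); bouts beyond
    it fall into the last, open-ended class.
    """
    sel = bouts[bouts["window"] == window]["duration_minutes"].to_numpy()
    if sel.size == 0:
        return pd.DataFrame(columns=["class_start_min", "class_end_min", "fraction"])
    top = max_minutes if max_minutes is not None else sel.max()
    n_classes = max(1, int(np.ceil(top / interval_minutes - 1e-9)))
    edges = np.arange(n_classes + 1) * interval_minutes
    idx = np.minimum((sel / interval_minutes - 1e-9).astype(int), n_classes - 1)
    frac = np.bincount(idx, minlength=n_classes) / sel.size
    return pd.DataFrame(
        {
            "class_start_min": edges[:-1],
            "class_end_min": edges[1:],
            "fraction": frac,
        }
    )


def threshold_sensitivity(
    trace: MobilityTrace,
    thresholds: tuple[float, ...] = (0.90, 0.95, 0.97),
    baseline: float = 0.95,
    min_seconds: float = 40.0,
) -> dict:
    """Sleep metric panel per immobility threshold, with % deltas vs baseline.

    Delta% = 100 * (metric(t) - metric(baseline)) / metric(baseline);
    NaN where the baseline metric is zero (undefined, flagged).
    """
    metrics = {}
    for t in sorted(set(thresholds) | {baseline}):
        metrics[t] = sleep_metrics(score_sleep(trace, threshold=t, min_seconds=min_seconds))
    base = metrics[baseline].as_dict()
    deltas = {}
    for t in thresholds:
        cur = metrics[t].as_dict()
        deltas[t] = {
            k: (100.0 * (cur[k] - base[k]) / base[k]) if base.get(k) else np.nan
            for k in base
        }
    return {"metrics": metrics, "delta_pct_vs_baseline": deltas, "baseline": baseline}
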