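"""Photic responses: light-pulse phase shifts and skeleton-photoperiod entrainment.

The phase shift of a free-running rhythm to a discrete light pulse
(classically 10 min, 100 lux, at CT 16) is estimated Aschoff type-II
style: regression lines are fit through the activity onsets of the days
before and after the pulse (excluding post-pulse transient cycles), both
lines are extrapolated to the first post-pulse day, and the shift is the
difference between the extrapolations.  Positive values are phase
delays (onsets moved later).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity_metrics import OnsetParams, detect_onsets, unwrap_onsets
from .errors import InsufficientDataError, ValidationError
from .schedule import Regime
from .timeseries import ActivityRecord, fold_days
from .activity_metrics import _window_activity_pct


@dataclass
class PhaseShiftResult:
    delay_minutes: float  # positive = delay
    pre_fit: tuple[float, float]  # (slope min/day, intercept min)
    post_fit: tuple[float, float]
    pulse_day: int
    transient_days_excluded: int
    n_pre: int
    n_post: int


def _fit_line(days: np.ndarray, onsets: np.ndarray, side: str, min_fit_days: int):
    ok = np.isfinite(onsets)
    if ok.sum() < min_fit_days:
        raise InsufficientDataError(
            f"insufficient onsets on the {side} side: {int(ok.sum())} < {min_fit_days}"
        )
    slope, intercept = np.polyfit(days[ok], onsets[ok], 1)
    return float(slope), float(intercept), int(ok.sum())


def phase_shift(
    record: ActivityRecord,
    pulse_day: int,
    pre_days: int = 7,
    post_days: int = 7,
    transient_days: int = 2,
    min_fit_days: int = 5,
    onset_params: OnsetParams | None = None,
    subbin: bool = True,
) -> PhaseShiftResult:
    """Estimate the phase shift produced by a pulse given on ``pulse_day``.

    The pre-pulse line uses the ``pre_days`` onsets ending on the pulse
    day (the pulse falls after that day's onset); the post-pulse line
    uses ``post_days`` onsets beginning after ``transient_days``
    relaxation cycles.  Both are extrapolated to day ``pulse_day + 1``.
    Sub-bin onset refinement is on by default so that bin quantization
    does not floor the estimate.
    """
    dm = fold_days(record)
    onsets = detect_onsets(dm, onset_params, subbin=subbin)
    onsets = unwrap_onsets(onsets)
    days = dm.days.astype(float)

    pre_mask = (days > pulse_day - pre_days) & (days <= pulse_day)
    post_start = pulse_day + 1 + transient_days
    post_mask = (days >= post_start) & (days < post_start + post_days)
    s_pre, b_pre, n_pre = _fit_line(days[pre_mask], onsets[pre_mask], "pre", min_fit_days)
    s_post, b_post, n_post = _fit_line(days[post_mask], onsets[post_mask], "post", min_fit_days)

    target = pulse_day + 1.0
    delay = (s_post * target + b_post) - (s_pre * target + b_pre)
    return PhaseShiftResult(
        delay_minutes=float(delay),
        pre_fit=(s_pre, b_pre),
        post_fit=(s_post, b_post),
        pulse_day=pulse_day,
        transient_days_excluded=transient_days,
        n_pre=n_pre,
        n_post=n_post,
    )


def subjective_night_activity(record: ActivityRecord, per_day: bool = False):
    """% of activity in the declared subjective night under a skeleton photoperiod.

    The subjective night is the 12-h window between the evening and
    morning pulses corresponding to the prior dark phase.
    """
    if record.schedule.regime is not Regime.SKELETON:
        raise ValidationError("subjective-night activity requires a SKELETON schedule")
    return _window_activity_pct(record, per_day=per_day)
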