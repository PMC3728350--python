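"""Sokolove–Bushell chi-square periodogram and rhythm power.

For a candidate period of ``p`` bins the series is folded into ``K``
complete cycles (the incomplete final cycle is dropped, keeping the
chi-square null exact) and

    Qp = n' * sum_h K_h (M_h - Mbar)^2 / sum_i (x_i - Mbar)^2

where ``M_h`` are the p column means, ``K_h`` the replicates behind
each column mean (K everywhere in a gap-free record), ``Mbar`` the
grand mean and ``n' = K*p`` the number of points examined (reduced
when gaps are present).  The numerator sum is the between-columns sum
of squares of the folded one-way layout, so Qp = n' * (between SS) /
(total SS), reaching n' for a perfectly repeating waveform — hence
the %V power normalization below is bounded by 100.
Under white noise Qp is asymptotically chi-square with
``p - 1`` degrees of freedom, which supplies the 0.05 significance
line.  The free-running period tau is the candidate with the largest
Qp among those exceeding the line (smallest period wins ties), and the
rhythm power is reported as %V = Qp(tau) * 100 / n'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .timeseries import ActivityRecord


@dataclass
class PeriodogramResult:
    candidate_periods: np.ndarray  # hours, ascending
    qp: np.ndarray
    sig_line: np.ndarray
    n_per_candidate: np.ndarray  # points examined at each candidate
    alpha: float
    tau_hours: float | None
    power_pct: float | None
    n_points: int | None  # points examined at the peak
    peak_index: int | None

    @property
    def is_rhythmic(self) -> bool:
        return self.tau_hours is not None


def power_pct(qp_peak: float, n: int) -> float:
    """%V normalization of the periodogram amplitude: Qp * 100 / n."""
    if n <= 0:
        raise ValidationError("n must be positive")
    if qp_peak < 0:
        raise ValidationError("Qp must be non-negative")
    return qp_peak * 100.0 / n


def chi_square_periodogram(
    record: ActivityRecord,
    min_period_h: float = 20.0,
    max_period_h: float = 28.0,
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Scan candidate periods (integer bin multiples) over the given range.

    The record must span at least two full cycles of the longest
    candidate.  Gaps (NaN bins) are excluded from the means and reduce
    n'.  A constant (zero-variance) series yields a defined arrhythmic
    result with Qp = 0 everywhere and absent tau.
    """
    x = record.counts
    n_total = x.size
    bin_h = record.bin_minutes / 60.0
    if record.duration_hours < 2.0 * max_period_h:
        raise InsufficientDataError(
            f"record spans {record.duration_hours:.1f} h; need >= {2 * max_period_h:.1f} h"
        )
    p_min = int(np.ceil(min_period_h / bin_h - 1e-9))
    p_max = int(np.floor(max_period_h / bin_h + 1e-9))
    if p_min < 2 or p_max < p_min:
        raise ValidationError("empty candidate range at this bin width")

    periods = np.empty(p_max - p_min + 1)
    qp = np.empty_like(periods)
    sig = np.empty_like(periods)
    n_used = np.empty(periods.size, dtype=int)
    for i, p in enumerate(range(p_min, p_max + 1)):
        k = n_total // p
        xs = x[: k * p].reshape(k, p)
        valid = np.isfinite(xs)
        n_valid = int(valid.sum())
        n_per_col = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            col_means = np.nanmean(xs, axis=0)
            grand = np.nanmean(xs)
            denom = np.nansum((xs - grand) ** 2)
            num = np.nansum(n_per_col * (col_means - grand) ** 2)
        periods[i] = p * bin_h
        n_used[i] = n_valid
        qp[i] = 0.0 if denom == 0 or n_valid == 0 else n_valid * num / denom
        sig[i] = stats.chi2.ppf(1.0 - alpha, p - 1)

    significant = qp > sig
    if significant.any():
        # argmax over masked Qp returns the first (= smallest-period) maximum
        masked = np.where(significant, qp, -np.inf)
        peak = int(np.argmax(masked))
        tau = float(periods[peak])
        n_peak = int(n_used[peak])
        pwr = power_pct(float(qp[peak]), n_peak)
    else:
        peak = None
        tau = None
        n_peak = None
        pwr = None
    return PeriodogramResult(
        candidate_periods=periods,
        qp=qp,
        sig_line=sig,
        n_per_candidate=n_used,
        alpha=alpha,
        tau_hours=tau,
        power_pct=pwr,
        n_points=n_peak,
        peak_index=peak,
    )
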