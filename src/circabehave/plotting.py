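"""Basic chronobiology plots: double-plotted actogram and periodogram."""

from __future__ import annotations

import numpy as np

from .periodogram import PeriodogramResult
from .timeseries import DayMatrix


def plot_actogram(day_matrix: DayMatrix, ax=None, color: str = "k"):
    """Double-plotted actogram: each row shows 48 h (day d, then day d+1)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * day_matrix.n_days + 1))
    v = np.nan_to_num(day_matrix.values)
    vmax = v.max() or 1.0
    bpd = v.shape[1]
    hours = np.arange(2 * bpd) * day_matrix.bin_minutes / 60.0
    for d in range(day_matrix.n_days):
        row = v[d]
        nxt = v[d + 1] if d + 1 < day_matrix.n_days else np.zeros(bpd)
        both = np.concatenate([row, nxt]) / vmax
        ax.fill_between(hours, d, d + np.clip(both, 0, 1) * 0.9, step="post", color=color, lw=0)
    ax.set_ylim(day_matrix.n_days, 0)
    ax.set_xlim(0, 48)
    ax.set_xticks(np.arange(0, 49, 6))
    ax.set_xlabel("hours (double plot)")
    ax.set_ylabel("day")
    return ax


def plot_periodogram(result: PeriodogramResult, ax=None):
    """Qp vs candidate period with the diagonal 0.05 significance line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.candidate_periods, result.qp, color="k", lw=1, label="Qp")
    ax.plot(result.candidate_periods, result.sig_line, color="r", lw=1,
            label=f"P<{result.alpha:g}")
    if result.tau_hours is not None:
        ax.axvline(result.tau_hours, color="b", ls=":", lw=1)
        ax.set_title(f"tau = {result.tau_hours:.2f} h, power = {result.power_pct:.1f}%V")
    else:
        ax.set_title("arrhythmic (no candidate above the significance line)")
    ax.set_xlabel("period (h)")
    ax.set_ylabel("Qp")
    ax.legend(frameon=False)
    return ax
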