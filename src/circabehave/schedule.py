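"""Lighting schedules and the ZT time frame.

Zeitgeber time (ZT) is anchored to lights-on: ZT0 = lights-on, ZT12 =
lights-off under a 12:12 light:dark (LD) cycle.  Under constant darkness
(DD) the same 24-h frame is retained as "projected" ZT from the last LD
cycle, with a declared 12-h subjective night.  A skeleton photoperiod
replaces the 12-h light phase with two 1-h pulses framing it
(1:11:1:11 LDLD).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ValidationError

CYCLE_HOURS = 24.0


class Regime(str, Enum):
    LD = "LD"
    DD = "DD"
    SKELETON = "SKELETON"


@dataclass(frozen=True)
class LightSchedule:
    """Photic regime over a fixed 24.0-h frame.

    Parameters
    ----------
    regime
        LD, DD or SKELETON.
    lights_on
        Intervals ``(start_hour, end_hour)`` of light within [0, 24).
        LD carries exactly one 12-h interval; SKELETON exactly two 1-h
        pulses separated by 11-h gaps; DD none.
    subjective_night
        12-h window used as "night" when no true dark phase defines one
        (DD, SKELETON).  For LD the dark window is the complement of the
        light interval and this field is ignored.
    """

    regime: Regime
    lights_on: tuple[tuple[float, float], ...] = ()
    subjective_night: tuple[float, float] = (12.0, 24.0)

    def __post_init__(self) -> None:
        for a, b in self.lights_on:
            if not (0.0 <= a < b <= CYCLE_HOURS):
                raise ValidationError(f"light interval ({a}, {b}) outside [0, 24]")
        ivs = sorted(self.lights_on)
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if b1 > a2:
                raise ValidationError("light intervals overlap")
        if self.regime is Regime.LD:
            if len(ivs) != 1 or abs((ivs[0][1] - ivs[0][0]) - 12.0) > 1e-9:
                raise ValidationError("LD requires exactly one 12-h light interval")
        elif self.regime is Regime.DD:
            if ivs:
                raise ValidationError("DD carries no light intervals")
        elif self.regime is Regime.SKELETON:
            if len(ivs) != 2 or any(abs((b - a) - 1.0) > 1e-9 for a, b in ivs):
                raise ValidationError("SKELETON requires exactly two 1-h pulses")
            gap1 = ivs[1][0] - ivs[0][1]
            gap2 = CYCLE_HOURS - ivs[1][1] + ivs[0][0]
            if abs(gap1 - 11.0) > 1e-9 or abs(gap2 - 11.0) > 1e-9:
                raise ValidationError("SKELETON pulses must be separated by 11-h gaps")
        a, b = self.subjective_night
        if abs((b - a) - 12.0) > 1e-9:
            raise ValidationError("subjective night must span 12 h")

    # --- constructors -------------------------------------------------
    @classmethod
    def ld(cls, lights_on_hour: float = 0.0) -> "LightSchedule":
        """12:12 LD with lights-on at ``lights_on_hour`` (ZT0 by definition)."""
        a = lights_on_hour % CYCLE_HOURS
        return cls(Regime.LD, ((a, a + 12.0),), (a + 12.0, a + 24.0) if a == 0 else (12.0, 24.0))

    @classmethod
    def dd(cls, subjective_night: tuple[float, float] = (12.0, 24.0)) -> "LightSchedule":
        return cls(Regime.DD, (), subjective_night)

    @classmethod
    def skeleton(
        cls,
        pulses: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (12.0, 13.0)),
        subjective_night: tuple[float, float] = (12.0, 24.0),
    ) -> "LightSchedule":
        return cls(Regime.SKELETON, tuple(pulses), subjective_night)

    # --- derived windows ----------------------------------------------
    @property
    def night_window(self) -> tuple[float, float]:
        """The 12-h dark (LD) or declared subjective-night (DD/SKELETON) window.

        Returned as ``(start, end)`` in hours with ``end`` possibly > 24
        when the window wraps past midnight of the ZT frame.
        """
        if self.regime is Regime.LD:
            a, b = self.lights_on[0]
            return (b % CYCLE_HOURS, b % CYCLE_HOURS + 12.0)
        return self.subjective_night

    def night_mask(self, bin_minutes: float) -> np.ndarray:
        """Boolean mask over one day's bins: True where the bin midpoint is in night."""
        n = int(round(CYCLE_HOURS * 60.0 / bin_minutes))
        mid = (np.arange(n) + 0.5) * bin_minutes / 60.0
        a, b = self.night_window
        return ((mid - a) % CYCLE_HOURS) < (b - a)

    def is_light(self, hour: float) -> bool:
        h = hour % CYCLE_HOURS
        return any(a <= h < b for a, b in self.lights_on)
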