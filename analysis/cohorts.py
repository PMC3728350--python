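"""Shared cohort definitions for the analysis scripts.

Three synthetic genotype groups with a gene-dose gradient in circadian
robustness, patterned on a wheel-running study of young-adult mice:
the control group has a strongly nocturnal, consolidated rhythm; the
two mutant groups weaken it by degrees.  Group means are generator
settings, so every downstream metric has a known target.
"""

from dataclasses import dataclass

import numpy as np

import circabehave as cb

N_PER_GROUP = 8
N_DAYS = 10


@dataclass(frozen=True)
class GroupSpec:
    name: str
    tau_hours: float
    alpha_minutes: float
    active_rate: float  # counts/hr within the active phase
    nocturnality: float  # dark-phase share under LD
    onset_jitter_sd_min: float
    phase_delay_min: float  # imposed shift in the pulse assay
    subjective_night_share: float  # skeleton photoperiod
    day_sleep_fraction: float
    mean_sleep_bout_day_min: float


GROUPS = (
    GroupSpec("control", 23.62, 612.9, 2900.0, 0.975, 8.0, 113.0, 0.932, 0.60, 12.0),
    GroupSpec("het", 23.82, 550.9, 2800.0, 0.975, 10.0, 118.0, 0.966, 0.55, 10.0),
    GroupSpec("hom", 23.62, 598.3, 2600.0, 0.948, 14.0, 119.0, 0.937, 0.40, 6.0),
)


def animal_params(spec: GroupSpec, animal: int, seed: int, ld: bool) -> cb.ActivitySimParams:
    """Per-animal parameter draw around the group mean (seeded)."""
    rng = np.random.default_rng([seed, animal])
    return cb.ActivitySimParams(
        tau_hours=spec.tau_hours + rng.normal(0, 0.05),
        alpha_minutes=float(np.clip(spec.alpha_minutes + rng.normal(0, 25), 60, 1400)),
        mean_rate=float(np.clip(spec.active_rate + rng.normal(0, 200), 200, None)),
        nocturnality_target=spec.nocturnality if ld else None,
        onset_jitter_sd_min=spec.onset_jitter_sd_min,
        gap_rate_per_hr=0.5,
        mean_gap_min=8.0,
        noise="POISSON",
        seed=int(rng.integers(2**31)),
    )
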