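"""Lifecycle constants, the simulation clock, and the per-stage vital rates.

The simulated mosquito develops through egg, larva and pupa stages before
emerging as an adult that cycles through mate seeking, bloodmeal seeking,
digestion and oviposition (the gonotrophic cycle). The simulation runs at an
hourly resolution; several transitions are gated on simulated nighttime,
defined as 6 P.M. to 6 A.M.

All rates here are *daily* probabilities. Mortality is applied once per
simulated day (at noon) rather than being converted to hourly hazards.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LifeState",
    "Sex",
    "SimClock",
    "is_night",
    "hour_of_day",
    "sample_hatch_time",
    "adult_mortality_rate",
    "larval_mortality_rate",
    "biomass_weights",
    "EGG_BASE_HOURS",
    "PUPA_BASE_HOURS",
    "LARVA_DURATION_HOURS",
    "IMMATURE_DURATION_HOURS",
    "DIGEST_DURATION_HOURS",
    "HOST_FINDING_PROB",
    "EGG_DAILY_MORTALITY",
    "PUPA_DAILY_MORTALITY",
    "NIGHT_START_HOUR",
    "NIGHT_END_HOUR",
    "MORTALITY_HOUR",
    "MATING_HOUR",
    "RELEASE_HOUR",
    "CENSUS_HOUR",
]


class LifeState(enum.IntEnum):
    """Behavioural / life-stage states of a mosquito agent.

    Transitions only run forward along the lifecycle graph (egg -> larva ->
    pupa -> immature adult -> adult behaviours); DEAD is absorbing. Adult
    females cycle MATE_SEEKING -> BLOODMEAL_SEEKING -> BLOODMEAL_DIGESTING ->
    GRAVID -> BLOODMEAL_SEEKING until death; adult males remain MATE_SEEKING.
    """

    EGG = 0
    LARVA = 1
    PUPA = 2
    IMMATURE_ADULT = 3
    MATE_SEEKING = 4
    BLOODMEAL_SEEKING = 5
    BLOODMEAL_DIGESTING = 6
    GRAVID = 7
    DEAD = 8


class Sex(enum.IntEnum):
    MALE = 0
    FEMALE = 1


#: Hours added to the hatch-time draw for the egg and pupa stages ("1 day + Ht").
EGG_BASE_HOURS = 24
PUPA_BASE_HOURS = 24
#: Larval stage duration (12 days), exit gated on nighttime.
LARVA_DURATION_HOURS = 12 * 24
#: Immature adult maturation time before mate seeking.
IMMATURE_DURATION_HOURS = 53
#: Bloodmeal digestion time, exit gated on nighttime.
DIGEST_DURATION_HOURS = 36
#: Per-nighttime-hour probability that a seeking female finds a host.
HOST_FINDING_PROB = 0.25

EGG_DAILY_MORTALITY = 0.1
PUPA_DAILY_MORTALITY = 0.1

NIGHT_START_HOUR = 18  # 6 P.M.
NIGHT_END_HOUR = 6  # 6 A.M.
MORTALITY_HOUR = 12  # daily mortality pass at noon
RELEASE_HOUR = 15  # 3 P.M. daily male releases
CENSUS_HOUR = 15  # daily measures, counted immediately before the release
MATING_HOUR = 18  # females are assigned mates at 6 P.M.


def hour_of_day(hour_index: int) -> int:
    """Hour of day (0-23) for a simulation hour index; runs start at 00:00."""
    return int(hour_index) % 24


def is_night(hod) -> bool | np.ndarray:
    """Nighttime predicate: true on [18:00, 24:00) and [00:00, 06:00)."""
    hod = np.asarray(hod)
    out = (hod >= NIGHT_START_HOUR) | (hod < NIGHT_END_HOUR)
    return bool(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SimClock:
    """Simulated time: hours since the start of the run (start is 00:00)."""

    hour_index: int

    @property
    def hour_of_day(self) -> int:
        return hour_of_day(self.hour_index)

    @property
    def night(self) -> bool:
        return is_night(self.hour_of_day)


# ---------------------------------------------------------------------------
# Hatch time
# ---------------------------------------------------------------------------

_HT_BOUNDS = (0.5, 0.85, 0.9, 0.94)
_HT_SLOPES = (40.0, 68.57, 480.0, 600.0, 2400.0)
_HT_INTERCEPTS = (0.0, -10.28, -360.0, -468.0, -2160.0)


def sample_hatch_time(x):
    """Hatch-time Ht (hours) from a uniform draw ``x`` in [0, 1].

    Piecewise-linear transform of a U(0,1) variate; most draws give hatch
    times under two days, with a long tail produced by the steep final
    branches. Branch boundaries at 0.5, 0.85, 0.9 and 0.94 (upper bounds
    inclusive). Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0.0) | (x > 1.0)):
        raise ValueError("hatch-time input must lie in [0, 1]")
    conds = [
        x <= _HT_BOUNDS[0],
        (x > _HT_BOUNDS[0]) & (x <= _HT_BOUNDS[1]),
        (x > _HT_BOUNDS[1]) & (x <= _HT_BOUNDS[2]),
        (x > _HT_BOUNDS[2]) & (x <= _HT_BOUNDS[3]),
        x > _HT_BOUNDS[3],
    ]
    vals = [s * x + b for s, b in zip(_HT_SLOPES, _HT_INTERCEPTS)]
    out = np.select(conds, vals)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Mortality rates
# ---------------------------------------------------------------------------


def adult_mortality_rate(age_days):
    """Daily adult mortality probability as a function of age in days.

    Senescent logistic-type curve: 0.1 at emergence, rising strictly with age
    toward an asymptote of 0.4. Accepts scalars or arrays.
    """
    n = np.asarray(age_days, dtype=float)
    if np.any(n < 0):
        raise ValueError("age_days must be nonnegative")
    # algebraically identical to 0.1 e^(n/25) / (1 + 0.25 (e^(n/25) - 1)),
    # written to stay finite for large ages
    out = 0.1 / (0.25 + 0.75 * np.exp(-n / 25.0))
    return float(out) if out.ndim == 0 else out


def larval_mortality_rate(age_days, l_mass, carrying_capacity):
    """Daily larval mortality probability, density dependent and age biased.

    ``0.1 * exp(L_mass / (n * C))`` clamped to 1. Mortality grows with total
    habitat biomass ``L_mass`` relative to the carrying capacity ``C`` and
    falls with larval age ``n`` (days), so crowding hits young larvae hardest.
    """
    if carrying_capacity <= 0:
        raise ValueError("carrying capacity must be positive")
    n = np.asarray(age_days, dtype=float)
    if np.any(n <= 0):
        raise ValueError("larval age in days must be positive")
    out = np.minimum(1.0, 0.1 * np.exp(np.asarray(l_mass, dtype=float) / (n * carrying_capacity)))
    return float(out) if out.ndim == 0 else out


def biomass_weights(day_ages):
    """Biomass weight of larvae by integer day age.

    A larva of day-age n contributes weight n for n in 1..10; day-age 0
    contributes nothing and ages beyond 10 are clamped to 10 (larvae can
    linger past day 10 while waiting for a nighttime stage exit).
    """
    d = np.asarray(day_ages)
    return np.clip(d, 0, 10).astype(float)
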