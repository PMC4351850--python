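"""Campaign orchestration: burn-in, baseline census, releases, replicates.

A full experiment is: seed a small wild-type population, let it burn in to
a stationary state (default 180 days), average the wild-type adult male
count over the last 30 burn-in days, then release a fixed number of
homozygous mate-seeking males every day at 3 P.M. for the campaign period.
The release number is the baseline male average multiplied by the release
proportion, rounded to the nearest whole number, and stays fixed even as
the wild population is suppressed.

Daily measures are recorded at 15:00 with population counts taken *before*
the release and the fecundity potential *after* it. Reported experiment
outputs are across-replicate means of independently seeded treated and
control (no-intervention) runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genetics import HOMOZYGOUS, SITImplementation
from .lifecycle import CENSUS_HOUR, MORTALITY_HOUR, LifeState, Sex
from .metrics import (
    MeasureSeries,
    RAW_COLUMNS,
    SuppressionSummary,
    census_row,
    fecundity_potential,
    normalize,
    suppression_factor,
)
from .population import MosquitoAgent, Population

__all__ = [
    "CampaignConfig",
    "ReleaseSchedule",
    "ReplicateResult",
    "ExperimentResult",
    "compute_release_number",
    "baseline_male_average",
    "make_released_male",
    "replicate_seed",
    "run_replicate",
    "run_arm",
    "run_experiment",
]

#: Default carrying capacity; calibrated so the no-intervention equilibrium
#: sits near 500 wild-type adult females with the default clutch size of 60.
DEFAULT_CARRYING_CAPACITY = 15_000.0


@dataclass(frozen=True)
class CampaignConfig:
    """Everything needed to reproduce one experiment."""

    implementation: SITImplementation = SITImplementation.NONE
    release_proportion: float = 0.3
    released_competitiveness: float = 1.0
    burn_in_days: int = 180
    baseline_window_days: int = 30
    campaign_days: int = 365
    clutch_size: int = 60
    carrying_capacity: float = DEFAULT_CARRYING_CAPACITY
    initial_adults: int = 200
    replicates: int = 30
    master_seed: int = 0
    final_window_days: int = 30

    def __post_init__(self) -> None:
        if self.release_proportion < 0:
            raise ValueError("release proportion must be nonnegative")
        if not 0.0 <= self.released_competitiveness <= 1.0:
            raise ValueError("released competitiveness must lie in [0, 1]")
        if self.baseline_window_days > self.burn_in_days:
            raise ValueError("baseline window must lie inside the burn-in")
        if min(self.burn_in_days, self.campaign_days, self.baseline_window_days) <= 0:
            raise ValueError("all durations must be positive")
        if self.carrying_capacity <= 0 or self.clutch_size <= 0:
            raise ValueError("carrying capacity and clutch size must be positive")
        object.__setattr__(self, "implementation", SITImplementation(self.implementation))

    @property
    def control(self) -> "CampaignConfig":
        """The paired no-intervention configuration."""
        return replace(self, implementation=SITImplementation.NONE, release_proportion=0.0)


@dataclass(frozen=True)
class ReleaseSchedule:
    """Fixed daily release: the same number of males at 3 P.M. every day."""

    release_number: int
    release_hour: int = 15

    def __post_init__(self) -> None:
        if self.release_number < 0:
            raise ValueError("release number must be nonnegative")


def compute_release_number(avg_male_pop: float, proportion: float) -> int:
    """Daily release number: baseline male average x proportion, rounded to
    the nearest whole number (halves away from zero)."""
    if avg_male_pop <= 0:
        raise ValueError("average male population must be positive")
    if proportion < 0:
        raise ValueError("release proportion must be nonnegative")
    x = avg_male_pop * proportion
    return int(math.floor(x + 0.5))


def baseline_male_average(census: "np.ndarray | list") -> float:
    """Arithmetic mean of the daily wild-type adult male counts over the
    pre-campaign observation window."""
    census = np.asarray(census, dtype=float)
    if census.size == 0:
        raise ValueError("empty baseline census")
    return float(census.mean())


def make_released_male(config: CampaignConfig) -> MosquitoAgent:
    """One released male: homozygous for the lethal allele, mate seeking,
    age 0, with the configured competitiveness."""
    if config.implementation is SITImplementation.NONE:
        raise ValueError("no males are released without an SIT implementation")
    return MosquitoAgent(
        sex=Sex.MALE,
        genotype=HOMOZYGOUS,
        competitiveness=config.released_competitiveness,
        state=LifeState.MATE_SEEKING,
    )


def replicate_seed(master_seed: int, arm_key: tuple, replicate: int) -> np.random.SeedSequence:
    """Splittable per-replicate seed: SeedSequence(master, spawn_key=arm+(r,)).

    Treated and control arms use disjoint spawn keys, so they are independent
    (unpaired) streams.
    """
    return np.random.SeedSequence(master_seed, spawn_key=tuple(arm_key) + (replicate,))


@dataclass
class ReplicateResult:
    """One replicate's daily measures plus its calibration bookkeeping."""

    measures: MeasureSeries
    baseline_male_average: float
    release_number: int
    total_released: int
    failed_calibration: bool
    seed: object = None


def run_replicate(
    config: CampaignConfig,
    seed,
    log_events: bool = False,
) -> ReplicateResult:
    """Run burn-in, baseline census and one campaign; deterministic in
    (config, seed).

    Population extinction before the campaign starts is flagged as a failed
    calibration (the measures are still returned), not raised.
    """
    from .scenarios import generate_fixture_population

    rng = np.random.default_rng(seed)
    pop = Population(
        config.carrying_capacity,
        clutch_size=config.clutch_size,
        implementation=config.implementation,
        log_events=log_events,
    )
    pop.add_agents(generate_fixture_population(config.initial_adults, rng=rng), hour=0)

    baseline_start = config.burn_in_days - config.baseline_window_days
    baseline: list[int] = []
    rows: list[dict] = []
    release_number = 0
    failed = False
    total_hours = (config.burn_in_days + config.campaign_days) * 24

    for hour in range(total_hours):
        day, hod = divmod(hour, 24)
        pop.step_hour(hour, rng)
        if hod == MORTALITY_HOUR:
            pop.apply_mortality(hour, rng)
        if hod != CENSUS_HOUR:
            continue
        if baseline_start <= day < config.burn_in_days:
            baseline.append(pop.adult_count(sex=Sex.MALE, alleles=0))
        if day == config.burn_in_days and hour % 24 == CENSUS_HOUR and not rows:
            # first campaign day: fix the release schedule from the baseline
            avg = baseline_male_average(baseline)
            if pop.adult_count() == 0 or avg <= 0:
                failed = True
                release_number = 0
            elif config.implementation is not SITImplementation.NONE:
                release_number = compute_release_number(avg, config.release_proportion)
        if day >= config.burn_in_days:
            row = census_row(pop)  # counts taken before the release
            if release_number > 0:
                pop.release_males(release_number, config.released_competitiveness, hour)
            row["raw_v_fecundity_potential"] = fecundity_potential(*pop.mate_seeking_males())
            row["day"] = day - config.burn_in_days
            rows.append(row)

    measures = pd.DataFrame(rows).set_index("day")[RAW_COLUMNS + ["raw_homo_larval_females", "raw_homo_larval_males"]]
    return ReplicateResult(
        measures=measures,
        baseline_male_average=baseline_male_average(baseline) if baseline else 0.0,
        release_number=release_number,
        total_released=pop.total_released,
        failed_calibration=failed,
        seed=seed,
    )


def run_arm(config: CampaignConfig, arm_key: tuple, replicates: int | None = None) -> list[ReplicateResult]:
    """Run ``replicates`` independently seeded replicates of one arm."""
    reps = config.replicates if replicates is None else replicates
    if reps < 1:
        raise ValueError("replicates must be >= 1")
    return [run_replicate(config, replicate_seed(config.master_seed, arm_key, r)) for r in range(reps)]


def _mean_measures(results: list[ReplicateResult]) -> MeasureSeries:
    stacked = pd.concat([r.measures for r in results], keys=range(len(results)))
    return stacked.groupby(level=1).mean()


@dataclass
class ExperimentResult:
    """Replicate-averaged treated and control series plus normalization."""

    config: CampaignConfig
    treated_mean: MeasureSeries
    control_mean: MeasureSeries
    normalized: MeasureSeries
    treated: list[ReplicateResult]
    control: list[ReplicateResult]

    def suppression(self, window_days: int | None = None) -> SuppressionSummary:
        if window_days is None:
            window_days = min(self.config.final_window_days, len(self.treated_mean))
        return suppression_factor(
            self.treated_mean,
            self.control_mean,
            window_days,
            implementation=self.config.implementation,
            release_proportion=self.config.release_proportion,
            competitiveness=self.config.released_competitiveness,
        )


def run_experiment(config: CampaignConfig, control_results: list[ReplicateResult] | None = None) -> ExperimentResult:
    """Run the treated and control arms and average across replicates.

    Treated replicates use spawn keys (0, r), controls (1, r); a precomputed
    control arm (e.g. shared across sweep cells) can be passed in.
    """
    treated = run_arm(config, arm_key=(0,))
    if control_results is None:
        control_results = run_arm(config.control, arm_key=(1,))
    treated_mean = _mean_measures(treated)
    control_mean = _mean_measures(control_results)
    normalized = normalize(treated_mean, control_mean)
    return ExperimentResult(
        config=config,
        treated_mean=treated_mean,
        control_mean=control_mean,
        normalized=normalized,
        treated=treated,
        control=control_results,
    )
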