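"""The individual-based population engine.

Agents are stored as a structure of arrays and every hour's state
transitions are applied simultaneously in vectorized batches, which keeps
desk-scale populations (tens of thousands of aquatic agents) fast and
removes any dependence on agent iteration order. The only operation where
order could matter — mate assignment — is performed as a single weighted
batch draw over the whole mate-seeking pool.

Hourly logic (one call to :meth:`Population.step_hour` per simulated hour):

* eggs hatch after 24 h + Ht regardless of time of day; carriers blocked in
  the egg are removed at that moment instead of hatching;
* larvae pupate after 12 days at the first nighttime hour;
* pupae emerge after 24 h + a fresh Ht draw at the first nighttime hour;
  carriers blocked in the pupa are removed at that moment;
* immature adults become mate seeking after 53 h;
* at 18:00 every mate-seeking female is assigned a competitiveness-weighted
  mate (males stay mate seeking);
* bloodmeal-seeking females find a host with probability 0.25 per nighttime
  hour; digestion takes 36 h and completes at a nighttime hour; gravid
  females deposit their whole clutch at the first nighttime hour and return
  to bloodmeal seeking.

All mortality is applied in a single daily pass (:meth:`apply_mortality`):
eggs and pupae die at 0.1/day, adults by the age-dependent senescence curve,
larvae by the density-dependent rate using the habitat biomass evaluated
once at the start of the pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import lifecycle as lc
from .genetics import Fate, Genotype, SITImplementation, fate_codes
from .lifecycle import (
    DIGEST_DURATION_HOURS,
    EGG_BASE_HOURS,
    HOST_FINDING_PROB,
    IMMATURE_DURATION_HOURS,
    LARVA_DURATION_HOURS,
    LifeState,
    MATING_HOUR,
    PUPA_BASE_HOURS,
    Sex,
    adult_mortality_rate,
    biomass_weights,
    is_night,
    sample_hatch_time,
)

__all__ = ["MosquitoAgent", "LarvalHabitat", "Population", "larval_biomass", "advance_agent"]

#: Sentinel exit hour for states with no scheduled exit (mate-seeking males, DEAD).
NEVER = np.int64(2**62)

_ADULT_STATES = (
    LifeState.IMMATURE_ADULT,
    LifeState.MATE_SEEKING,
    LifeState.BLOODMEAL_SEEKING,
    LifeState.BLOODMEAL_DIGESTING,
    LifeState.GRAVID,
)

# States whose exit condition carries a nighttime gate.
_NIGHT_GATED = np.zeros(len(LifeState), dtype=bool)
for _s in (
    LifeState.LARVA,
    LifeState.PUPA,
    LifeState.BLOODMEAL_SEEKING,
    LifeState.BLOODMEAL_DIGESTING,
    LifeState.GRAVID,
):
    _NIGHT_GATED[_s] = True


@dataclass
class MosquitoAgent:
    """One mosquito, in agent-object form.

    The engine stores agents as arrays; this dataclass is the convenient
    boundary representation used for construction (fixtures, released males)
    and for inspecting individuals in tests.
    """

    sex: Sex
    genotype: Genotype
    competitiveness: float = 1.0
    state: LifeState = LifeState.EGG
    age_days: float = 0.0
    state_entry_hour: int = 0
    hatch_time_hours: float = 0.0
    clutch_remaining: int = 0
    sire_genotype: Optional[Genotype] = None
    sire_competitiveness: Optional[float] = None
    fate: Fate = Fate.UNAFFECTED
    id: int = -1

    def __post_init__(self) -> None:
        if not 0.0 <= self.competitiveness <= 1.0:
            raise ValueError("competitiveness must lie in [0, 1]")
        if self.age_days < 0:
            raise ValueError("age_days must be nonnegative")
        if self.sex is Sex.MALE and self.sire_genotype is not None:
            raise ValueError("males never carry a sire record")


@dataclass
class LarvalHabitat:
    """The (single) larval habitat: a carrying capacity and the larvae in it."""

    carrying_capacity: float
    population: "Population" = None

    def __post_init__(self) -> None:
        if self.carrying_capacity <= 0:
            raise ValueError("carrying capacity must be positive")

    def larva_day_ages(self, hour: int | None = None) -> np.ndarray:
        """Integer day ages (as larvae, i.e. days since hatch) of all live
        larvae at ``hour`` (default: now)."""
        pop = self.population
        if pop is None:
            return np.zeros(0, dtype=np.int64)
        if hour is None:
            hour = pop.hour
        n = pop.n
        sel = pop.state[:n] == LifeState.LARVA
        return ((hour - pop.stage_hour[:n][sel]) // 24).astype(np.int64)

    @property
    def l_mass(self) -> float:
        return larval_biomass(self)

    @property
    def mortality_factor(self) -> float:
        """The density-dependence driver L_mass / C."""
        return self.l_mass / self.carrying_capacity


def larval_biomass(habitat: LarvalHabitat, hour: int | None = None) -> float:
    """Age-weighted larval biomass: sum over day ages n of n * (count of
    n-day-old larvae), with n clamped to 1..10 contribution weights."""
    return float(biomass_weights(habitat.larva_day_ages(hour)).sum())


class Population:
    """Structure-of-arrays container and hourly update engine.

    Parameters
    ----------
    carrying_capacity
        Habitat constant C of the density-dependent larval mortality.
    clutch_size
        Eggs deposited per gonotrophic cycle.
    implementation
        Active SIT implementation; decides the cached fate of new offspring.
    log_events
        When true, every state transition is appended to :attr:`events` as
        ``(hour, agent_id, from_state, to_state)`` — used by soundness checks;
        off by default for speed.
    """

    _FIELDS = (
        ("id", np.int64),
        ("sex", np.int8),
        ("alleles", np.int8),  # lethal allele count 0/1/2
        ("comp", np.float64),
        ("state", np.int8),
        ("birth_hour", np.int64),
        ("stage_hour", np.int64),  # entry into the current macro-stage (larva / adult age clock)
        ("entry_hour", np.int64),
        ("exit_hour", np.int64),
        ("clutch", np.int32),
        ("sire_alleles", np.int8),  # -1 = unmated
        ("sire_comp", np.float64),
        ("fate", np.int8),
    )

    def __init__(
        self,
        carrying_capacity: float,
        clutch_size: int = 60,
        implementation: SITImplementation = SITImplementation.NONE,
        log_events: bool = False,
        capacity: int = 4096,
    ) -> None:
        if carrying_capacity <= 0:
            raise ValueError("carrying capacity must be positive")
        if clutch_size <= 0:
            raise ValueError("clutch size must be positive")
        self.carrying_capacity = float(carrying_capacity)
        self.clutch_size = int(clutch_size)
        self.implementation = SITImplementation(implementation)
        self.habitat = LarvalHabitat(self.carrying_capacity, self)
        self.n = 0
        self.hour = 0
        self._next_id = 0
        self.total_released = 0
        self.events: list[tuple[int, int, int, int]] = []
        self.log_events = bool(log_events)
        for name, dtype in self._FIELDS:
            setattr(self, name, np.zeros(capacity, dtype=dtype))

    # -- storage ------------------------------------------------------------

    def _grow(self, need: int) -> None:
        cap = len(self.id)
        if self.n + need <= cap:
            return
        new_cap = max(cap * 2, self.n + need)
        for name, _ in self._FIELDS:
            arr = getattr(self, name)
            new = np.zeros(new_cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)

    def add(
        self,
        *,
        sex,
        alleles,
        comp,
        state,
        birth_hour,
        entry_hour,
        exit_hour,
        clutch=0,
        sire_alleles=-1,
        sire_comp=np.nan,
        fate=0,
        stage_hour=None,
    ) -> np.ndarray:
        """Append a batch of agents (scalars broadcast); returns their ids."""
        sex = np.atleast_1d(np.asarray(sex))
        k = len(sex)
        self._grow(k)
        sl = slice(self.n, self.n + k)
        ids = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        self._next_id += k
        self.id[sl] = ids
        self.sex[sl] = sex
        self.alleles[sl] = alleles
        self.comp[sl] = comp
        self.state[sl] = state
        self.birth_hour[sl] = birth_hour
        self.stage_hour[sl] = birth_hour if stage_hour is None else stage_hour
        self.entry_hour[sl] = entry_hour
        self.exit_hour[sl] = exit_hour
        self.clutch[sl] = clutch
        self.sire_alleles[sl] = sire_alleles
        self.sire_comp[sl] = sire_comp
        self.fate[sl] = fate
        self.n += k
        return ids

    def add_agents(self, agents, hour: int | None = None) -> np.ndarray:
        """Append :class:`MosquitoAgent` objects, deriving array fields."""
        if hour is None:
            hour = self.hour
        agents = list(agents)
        if not agents:
            return np.zeros(0, dtype=np.int64)
        ids = []
        for a in agents:
            dur = self._initial_exit(a, hour)
            ids.append(
                self.add(
                    sex=int(a.sex),
                    alleles=a.genotype.lethal_count,
                    comp=a.competitiveness,
                    state=int(a.state),
                    birth_hour=hour - int(round(a.age_days * 24)),
                    entry_hour=a.state_entry_hour if a.state_entry_hour else hour,
                    exit_hour=dur,
                    clutch=a.clutch_remaining,
                    sire_alleles=(a.sire_genotype.lethal_count if a.sire_genotype is not None else -1),
                    sire_comp=(a.sire_competitiveness if a.sire_competitiveness is not None else np.nan),
                    fate=int(a.fate),
                )[0]
            )
        return np.asarray(ids, dtype=np.int64)

    def _initial_exit(self, a: MosquitoAgent, hour: int) -> np.int64:
        s = a.state
        if s is LifeState.EGG:
            return np.int64(hour + int(np.ceil(EGG_BASE_HOURS + a.hatch_time_hours)))
        if s is LifeState.LARVA:
            return np.int64(hour + LARVA_DURATION_HOURS)
        if s is LifeState.PUPA:
            return np.int64(hour + int(np.ceil(PUPA_BASE_HOURS + a.hatch_time_hours)))
        if s is LifeState.IMMATURE_ADULT:
            return np.int64(hour + IMMATURE_DURATION_HOURS)
        if s is LifeState.BLOODMEAL_DIGESTING:
            return np.int64(hour + DIGEST_DURATION_HOURS)
        if s in (LifeState.BLOODMEAL_SEEKING, LifeState.GRAVID):
            return np.int64(hour)
        return NEVER  # MATE_SEEKING (exit handled by the mating phase), DEAD

    def get_agent(self, idx: int) -> MosquitoAgent:
        """Agent-object view of row ``idx`` (a copy, not a live view)."""
        sire = int(self.sire_alleles[idx])
        return MosquitoAgent(
            sex=Sex(int(self.sex[idx])),
            genotype=Genotype(int(self.alleles[idx])),
            competitiveness=float(self.comp[idx]),
            state=LifeState(int(self.state[idx])),
            age_days=(self.hour - int(self.birth_hour[idx])) / 24.0,
            state_entry_hour=int(self.entry_hour[idx]),
            clutch_remaining=int(self.clutch[idx]),
            sire_genotype=(Genotype(sire) if sire >= 0 else None),
            sire_competitiveness=(float(self.sire_comp[idx]) if sire >= 0 else None),
            fate=Fate(int(self.fate[idx])),
            id=int(self.id[idx]),
        )

    # -- event helpers ------------------------------------------------------

    def _record(self, sel: np.ndarray, frm: np.ndarray | int, to: int) -> None:
        if not self.log_events or sel.size == 0:
            return
        frm = np.broadcast_to(np.asarray(frm), sel.shape)
        for i, f in zip(self.id[sel], frm):
            self.events.append((self.hour, int(i), int(f), int(to)))

    def _set_state(self, sel: np.ndarray, state: LifeState, hour: int, exit_hour) -> None:
        if sel.size == 0:
            return
        self._record(sel, self.state[sel], int(state))
        self.state[sel] = int(state)
        self.entry_hour[sel] = hour
        self.exit_hour[sel] = exit_hour

    def _kill(self, sel: np.ndarray) -> None:
        if sel.size == 0:
            return
        self._record(sel, self.state[sel], int(LifeState.DEAD))
        self.state[sel] = int(LifeState.DEAD)
        self.exit_hour[sel] = NEVER

    def compact(self) -> None:
        """Drop DEAD rows."""
        n = self.n
        keep = np.flatnonzero(self.state[:n] != LifeState.DEAD)
        if keep.size == n:
            return
        for name, _ in self._FIELDS:
            arr = getattr(self, name)
            arr[: keep.size] = arr[keep]
        self.n = keep.size

    # -- hourly update ------------------------------------------------------

    def step_hour(self, hour: int, rng: np.random.Generator) -> None:
        """Apply one hour of lifecycle transitions (no mortality)."""
        self.hour = hour
        hod = hour % 24
        night = is_night(hod)
        n = self.n
        st = self.state[:n]
        due = self.exit_hour[:n] <= hour
        if not night:
            due &= ~_NIGHT_GATED[st]
        idx = np.flatnonzero(due)
        if idx.size:
            sti = st[idx]  # states at the top of the hour; one transition max

            sel = idx[sti == LifeState.EGG]
            if sel.size:
                blocked = self.fate[sel] == Fate.BLOCKED_IN_EGG
                self._kill(sel[blocked])
                live = sel[~blocked]
                self._set_state(live, LifeState.LARVA, hour, hour + LARVA_DURATION_HOURS)
                self.stage_hour[live] = hour  # larval age clock starts at hatch

            sel = idx[sti == LifeState.LARVA]
            if sel.size:
                ht = sample_hatch_time(rng.random(sel.size))
                exits = hour + np.ceil(PUPA_BASE_HOURS + ht).astype(np.int64)
                self._set_state(sel, LifeState.PUPA, hour, exits)

            sel = idx[sti == LifeState.PUPA]
            if sel.size:
                blocked = self.fate[sel] == Fate.BLOCKED_IN_PUPA
                self._kill(sel[blocked])
                live = sel[~blocked]
                self._set_state(live, LifeState.IMMATURE_ADULT, hour, hour + IMMATURE_DURATION_HOURS)
                self.stage_hour[live] = hour  # adult age clock starts at emergence

            sel = idx[sti == LifeState.IMMATURE_ADULT]
            if sel.size:
                self._set_state(sel, LifeState.MATE_SEEKING, hour, NEVER)

            sel = idx[sti == LifeState.BLOODMEAL_SEEKING]
            if sel.size:
                fed = sel[rng.random(sel.size) < HOST_FINDING_PROB]
                self._set_state(fed, LifeState.BLOODMEAL_DIGESTING, hour, hour + DIGEST_DURATION_HOURS)

            sel = idx[sti == LifeState.BLOODMEAL_DIGESTING]
            if sel.size:
                self.clutch[sel] = self.clutch_size
                self._set_state(sel, LifeState.GRAVID, hour, hour)

            sel = idx[sti == LifeState.GRAVID]
            if sel.size:
                self._lay_eggs(sel, hour, rng)
                self.clutch[sel] = 0
                self._set_state(sel, LifeState.BLOODMEAL_SEEKING, hour, hour)

        if hod == MATING_HOUR:
            self._mate(hour, rng)

    def _mate(self, hour: int, rng: np.random.Generator) -> None:
        n = self.n
        seeking = self.state[:n] == LifeState.MATE_SEEKING
        fem = np.flatnonzero(seeking & (self.sex[:n] == Sex.FEMALE))
        if fem.size == 0:
            return
        males = np.flatnonzero(seeking & (self.sex[:n] == Sex.MALE))
        if males.size == 0:
            return
        w = self.comp[males]
        total = w.sum()
        if total <= 0:
            return  # no male carries any weight; females wait for a later night
        sires = males[rng.choice(males.size, size=fem.size, p=w / total)]
        self.sire_alleles[fem] = self.alleles[sires]
        self.sire_comp[fem] = self.comp[sires]
        self._set_state(fem, LifeState.BLOODMEAL_SEEKING, hour, hour)

    def _lay_eggs(self, mothers: np.ndarray, hour: int, rng: np.random.Generator) -> None:
        counts = self.clutch[mothers].astype(np.int64)
        mothers = mothers[counts > 0]
        counts = counts[counts > 0]
        if mothers.size == 0:
            return
        if np.any(self.sire_alleles[mothers] < 0):
            raise RuntimeError("gravid female without a sire record")
        mom = np.repeat(mothers, counts)
        total = mom.size
        sexes = rng.integers(0, 2, size=total).astype(np.int8)
        m_draw = rng.random(total) < self.alleles[mom] / 2.0
        s_draw = rng.random(total) < self.sire_alleles[mom] / 2.0
        alleles = (m_draw.astype(np.int8) + s_draw.astype(np.int8)).astype(np.int8)
        comp = (self.comp[mom] + self.sire_comp[mom]) / 2.0
        fate = fate_codes(alleles, sexes, self.implementation)
        ht = sample_hatch_time(rng.random(total))
        exits = hour + np.ceil(EGG_BASE_HOURS + ht).astype(np.int64)
        ids = self.add(
            sex=sexes,
            alleles=alleles,
            comp=comp,
            state=int(LifeState.EGG),
            birth_hour=hour,
            entry_hour=hour,
            exit_hour=exits,
            fate=fate,
        )
        if self.log_events:
            for i in ids:
                self.events.append((hour, int(i), -1, int(LifeState.EGG)))

    # -- daily mortality ----------------------------------------------------

    def apply_mortality(self, hour: int, rng: np.random.Generator) -> None:
        """One daily mortality pass over the whole population.

        Eggs and pupae die at the fixed daily rate 0.1; adults at the
        age-dependent senescence rate (age on the adult clock, 0 at
        emergence); larvae at the density-dependent rate (age in days since
        hatch, clamped to at least 1) with the habitat biomass evaluated once
        at the start of the pass. Dead agents are removed from all
        collections.
        """
        n = self.n
        if n == 0:
            return
        st = self.state[:n]
        stage_age_days = (hour - self.stage_hour[:n]) / 24.0
        p = np.zeros(n)
        eggpupa = (st == LifeState.EGG) | (st == LifeState.PUPA)
        p[eggpupa] = lc.EGG_DAILY_MORTALITY
        adult = (st >= LifeState.IMMATURE_ADULT) & (st <= LifeState.GRAVID)
        if adult.any():
            p[adult] = adult_mortality_rate(stage_age_days[adult])
        larv = st == LifeState.LARVA
        if larv.any():
            day_age = np.floor(stage_age_days[larv])
            l_mass = float(biomass_weights(day_age).sum())
            n_eff = np.maximum(day_age, 1.0)
            arg = np.minimum(l_mass / (n_eff * self.carrying_capacity), 50.0)  # rate clamps to 1 well below this
            p[larv] = np.minimum(1.0, 0.1 * np.exp(arg))
        dead = np.flatnonzero((rng.random(n) < p) & (st != LifeState.DEAD))
        self._kill(dead)
        self.compact()

    # -- census helpers -----------------------------------------------------

    def count(self, states, sex=None, alleles=None) -> int:
        n = self.n
        if np.isscalar(states) or isinstance(states, LifeState):
            mask = self.state[:n] == int(states)
        else:
            mask = np.isin(self.state[:n], [int(s) for s in states])
        if sex is not None:
            mask &= self.sex[:n] == int(sex)
        if alleles is not None:
            mask &= self.alleles[:n] == int(alleles)
        return int(mask.sum())

    def adult_count(self, sex=None, alleles=None) -> int:
        return self.count(_ADULT_STATES, sex=sex, alleles=alleles)

    def larva_count(self, sex=None, alleles=None) -> int:
        return self.count(LifeState.LARVA, sex=sex, alleles=alleles)

    def mate_seeking_males(self) -> tuple[np.ndarray, np.ndarray]:
        """(lethal allele counts, competitiveness) of the current mate-seeking
        male pool — the inputs of the fecundity-potential statistic."""
        n = self.n
        sel = (self.state[:n] == LifeState.MATE_SEEKING) & (self.sex[:n] == Sex.MALE)
        return self.alleles[:n][sel].copy(), self.comp[:n][sel].copy()

    def release_males(self, count: int, competitiveness: float, hour: int | None = None) -> None:
        """Inject ``count`` homozygous, mate-seeking adult males (age 0)."""
        if count <= 0:
            return
        if hour is None:
            hour = self.hour
        self.add(
            sex=np.full(count, int(Sex.MALE), dtype=np.int8),
            alleles=2,
            comp=competitiveness,
            state=int(LifeState.MATE_SEEKING),
            birth_hour=hour,
            entry_hour=hour,
            exit_hour=NEVER,
        )
        self.total_released += int(count)


def advance_agent(agent: MosquitoAgent, clock, habitat: LarvalHabitat | None, rng: np.random.Generator):
    """Apply one hour of lifecycle logic to a single agent.

    Scalar convenience wrapper over the batch engine: the agent is placed in
    a one-agent population and stepped one hour. Returns ``(updated_agent,
    deposited_eggs)`` where ``deposited_eggs`` is the number of eggs the
    agent laid this hour (gravid females). Mate seeking cannot resolve here
    (there is no male pool); use :class:`Population` for mating dynamics.
    """
    if agent.state is LifeState.DEAD:
        raise ValueError("cannot advance a DEAD agent")
    hour = clock.hour_index if hasattr(clock, "hour_index") else int(clock)
    cc = habitat.carrying_capacity if habitat is not None else 1.0
    pop = Population(cc, log_events=True)
    pop.hour = hour
    pop.add_agents([agent], hour=agent.state_entry_hour if agent.state_entry_hour else hour)
    # restore the true timing bookkeeping
    pop.birth_hour[0] = hour - int(round(agent.age_days * 24))
    pop.stage_hour[0] = pop.birth_hour[0]
    pop.entry_hour[0] = agent.state_entry_hour
    pop.exit_hour[0] = pop._initial_exit(agent, agent.state_entry_hour)
    before = pop.n
    pop.step_hour(hour, rng)
    laid = pop.n - before
    if pop.state[0] == LifeState.DEAD:
        out = agent
        out.state = LifeState.DEAD
        return out, laid
    return pop.get_agent(0), laid
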