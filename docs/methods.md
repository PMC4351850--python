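# Methods

`sitsim` is an individual-based, hourly-resolution simulator of an
*Anopheles gambiae* population under sustained releases of transgenic
males carrying a single-locus, dominant, fully penetrant cell-lethal gene.
This note documents the model, its parameters and defaults, the numerical
choices, and what the simulator does and does not capture.

## Lifecycle model

Every mosquito is an explicit agent with a sex, a genotype (0, 1 or 2
copies of the lethal allele), a heritable mating-competitiveness value
`m ∈ [0, 1]`, a behavioural state and timing bookkeeping. Agents move
through the states

```
egg → larva → pupa → immature adult → mate seeking
                                        ├ (males: remain mate seeking)
                                        └ (females) → bloodmeal seeking →
                                          bloodmeal digesting → gravid →
                                          bloodmeal seeking → …
```

with death possible in every state. The clock ticks hourly; runs start at
00:00 and *nighttime* is 18:00–06:00. Stage durations and exit rules:

| state | duration | exit gate |
|---|---|---|
| egg | 24 h + `Ht` | none |
| larva | 12 days | nighttime |
| pupa | 24 h + `Ht` (fresh draw) | nighttime |
| immature adult | 53 h | none |
| mate seeking | — | females mate at 18:00; males stay |
| bloodmeal seeking | — | 25% success per nighttime hour |
| bloodmeal digesting | 36 h | nighttime |
| gravid | — | deposits full clutch at the first nighttime hour |

`Ht` is the hatch-time draw: a piecewise-linear transform of a U(0,1)
variate with branch boundaries at 0.5, 0.85, 0.9 and 0.94 and slopes
40, 68.57, 480, 600 and 2400 (intercepts 0, −10.28, −360, −468, −2160).
Most draws fall below two days; the steep final branches produce a long
tail reaching 240 h. Two printed features of this curve are preserved
deliberately: it is continuous at 0.85/0.9/0.94 but has a finite jump at
x = 0.5 (20 h vs ≈ 24.005 h), and its tail exceeds the often-quoted
five-day maximum hatch time. Both are implemented exactly as printed and
asserted in the test suite rather than "fixed".

### Mortality

All mortality is applied in one daily pass at 12:00 noon, because every
rate in the model is a daily probability; converting to hourly hazards
would require an assumption the model does not state. Noon avoids
colliding with the 15:00 release/census, 18:00 mating, and the nighttime
transition window.

* Eggs and pupae: fixed 0.1/day.
* Adults: `M(n) = 0.1·e^(n/25) / (1 + 0.25·(e^(n/25) − 1))`, strictly
  increasing from 0.1 at emergence toward an asymptote of 0.4.
* Larvae: `M(n) = min(1, 0.1·e^(L_mass/(n·C)))`, density dependent and
  favouring older larvae. `L_mass = Σ_{n=1..10} n·L_n` is the age-weighted
  larval biomass and `C` the habitat carrying capacity.

**Age clocks.** The age `n` in each equation is the age on the clock of
the relevant stage: larval mortality and biomass use whole days since
hatching (a just-hatched larva has day-age 0 and contributes no biomass;
day-ages above 10 are clamped to weight 10 because larvae can outlive day
10 while waiting for a nighttime exit; the mortality denominator uses
`max(n, 1)`), and adult mortality uses days since emergence (so newly
emerged adults start at the 0.1 baseline, and released males enter at
adult age 0). The adult curve derives from adult survival analyses and is
parameterized from age 0, which only an adult-age clock reaches; the
biomass index range 1..10 likewise matches a larval-age clock spanning a
~12-day stage. An agent's total age since oviposition is tracked
separately as bookkeeping.

The biomass is evaluated once at the start of each mortality pass, so all
larvae in a pass face the same `L_mass`.

## Genetics and mating

The transgene is a single locus with a dominant, 100%-penetrant lethal
allele. Offspring draw one allele uniformly from each parent; sex is a
fair coin; competitiveness is the parental mean. An agent's developmental
fate is a pure function of (genotype, sex, implementation) and is cached
at conception:

* **EBS / EFK (early acting)** — affected carriers halt in the egg and are
  removed when the egg stage would have ended: they never enter the
  habitat and contribute no larval competition.
* **LBS / LFK (late acting)** — affected carriers develop as normal larvae
  (full biomass contribution — the central density-dependence mechanism)
  and are removed at the pupal-exit moment.
* **Female killing (EFK / LFK)** — only female carriers are affected;
  male carriers develop normally and propagate the allele.

At 18:00 each day every mate-seeking female is assigned a mate drawn from
the whole mate-seeking male pool with probability `m_i / Σ m_j`. Mating
is always successful; males remain available; females mate exactly once
and store the sire's genotype and competitiveness for all subsequent
clutches. A female finding no males (or a zero-total-weight pool) simply
waits for a later 18:00. Female competitiveness never affects her mating
probability, only her offspring's inherited value.

## Campaigns

A full experiment is: (1) seed a small wild-type population and burn in
for 180 days to a stationary state, (2) average the wild-type adult male
count over the last 30 burn-in days at the 15:00 census hour, (3) release
`round(proportion × baseline average)` homozygous, mate-seeking,
adult-age-0 males at 15:00 every day of the campaign (rounding is
half-away-from-zero; the release number never adapts to suppression), and
(4) record the ten daily measures at 15:00, counting populations before
the release and the fecundity potential after it.

The fecundity potential of the mate-seeking male pool is

```
F = 1 − Σ(m_i·[hom_i])/Σm_i − Σ(m_i·[het_i])/(2·Σm_i)
```

i.e. one minus the competitiveness-weighted share of matings expected to
yield lethal-carrying female offspring (heterozygous sires transmit to
half their offspring, hence the factor 2). `F` is undefined for an empty
or zero-weight pool and is reported as missing on such days; downstream
averages skip missing values.

Treated measures are normalized day-by-day against the across-replicate
mean of an independently seeded no-intervention control arm; transgenic
population classes are normalized with the control's wild-type numbers.
The suppression factor is the mean normalized wild-type adult female
count over the final 30 days (window configurable); elimination is
flagged when the raw treated mean over that window is exactly zero. The
"12th month" reading of the final window is interpreted as the last 30
days of the campaign.

## Defaults and calibration

| parameter | default | why |
|---|---|---|
| clutch size | 60 eggs/cycle | mid-range for *An. gambiae*; never printed in the source model |
| carrying capacity `C` | 15 000 | calibrated so the no-intervention equilibrium holds ≈ 500 wild-type adult females (desk scale) |
| initial adults | 200 | burn-in seed; half mated females mid-cycle, half mate-seeking males |
| burn-in | 180 days | stationarity well before the baseline window |
| baseline window | 30 days | pre-campaign male census |
| campaign | 365 days | one year of daily releases |
| replicates | 30 | reported results are replicate means |

The desk-scale calibration (~500 females, ~40–60 k live agents in the
aquatic stages) keeps a full replicate to a few seconds of CPU; the
acceptance runs use 10 replicates for onset lags (60-day campaigns) and 5
replicates for the proportion sweep (6-month campaigns). Absolute
population scale is a free parameter of the model; all reported measures
are either normalized or timing quantities that do not depend on it,
except as noted under limitations.

Seeding is splittable and documented: replicate `r` of arm `a` uses
`numpy.random.SeedSequence(master_seed, spawn_key=(a, r))`; treated and
control arms are unpaired, independent streams. A fixed (config, seed)
pair reproduces a trajectory bit for bit.

## Numerical and design choices

* The engine stores agents as a structure of arrays and applies each
  hour's transitions simultaneously in vectorized batches. This removes
  agent-iteration-order artifacts by construction; mate assignment — the
  only order-sensitive operation — is a single weighted batch draw.
* Scheduled exits are precomputed as hour indices (`ceil` of fractional
  durations), so an hourly gate test is a single integer comparison.
* The larval mortality expression can exceed 1 and is clamped to 1.
* A blocked-in-egg agent dies exactly when its egg stage would have
  ended; a blocked-in-pupa agent dies at its pupal-exit moment.
* Gravid females deposit the entire clutch in a single nighttime hour.
* An interrupted sweep resumes from per-cell cache files and yields the
  identical grid.

## What the generator emulates — and what it does not

The synthetic populations are closed, spatially unstructured and
climatically constant: one larval habitat with a fixed `C`, no
temperature or rainfall forcing, no migration, no adult dispersal, no
instar structure, no female remating, no accidental female releases, a
single lethal locus with complete penetrance, and malaria transmission
itself is out of scope. Passing tests therefore demonstrate the internal
population-dynamic and genetic mechanisms of the four SIT implementations
— onset lags, density-dependence exploitation by late-acting genes, the
heterozygous-male reservoir effect, dose response — not field-scale
predictions for any real release programme.

## Known limitations

* Two outcome features are sensitive to the source model's unprinted
  fecundity parameters (clutch size, carrying capacity and population
  scale of its companion description): the release proportion at which
  the LFK dose-response flattens, and the size of the brief early-EBS
  transient rise in the wild-type adult series. With the defaults above,
  the density-compensation headroom (free larval survival over
  equilibrium larval survival, ≈ 2×) is small, so the LFK sweep already
  flattens by proportion 0.3 (the corresponding acceptance check is left
  failing rather than tuned), and the EBS transient — while present with
  the expected ~2–3-week timing — is only a few percent above baseline
  and sits near the replicate noise floor at 10 replicates. Both
  behaviours scale with per-clutch fecundity, not with `C`.
* Elimination at desk scale is aided by demographic stochasticity in a
  way it would not be at field scale.
* The hatch-time curve is used exactly as printed, including its jump at
  x = 0.5 and its 10-day tail.
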