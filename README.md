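# sitsim

Agent-based simulation of transgenic sterile-insect-technique (SIT)
campaigns against *Anopheles gambiae*.

Transgenic SIT releases male mosquitoes homozygous for a dominant
cell-lethal gene so that their matings with wild females yield no viable
offspring, or no female offspring. `sitsim` is for vector-control
modellers who want to compare the four canonical implementations of this
idea — early/late acting × bisex/female-killing (EBS, EFK, LBS, LFK) —
in an individual-based *An. gambiae* population with an explicit hourly
lifecycle, density-dependent larval mortality, heritable mating
competitiveness and daily fixed-number male releases.

## The model in brief

Each mosquito is an agent moving through egg → larva → pupa → immature
adult → adult gonotrophic cycling, with nighttime-gated transitions and
an hourly clock. Mortality is daily: eggs/pupae at 0.1, adults at the
senescent rate

    M_adult(n) = 0.1·e^(n/25) / (1 + 0.25·(e^(n/25) − 1)),

and larvae at the density-dependent, older-favouring rate

    M_larva(n) = min(1, 0.1·e^(L_mass/(n·C))),   L_mass = Σ_{n=1..10} n·L_n,

where `C` is the habitat carrying capacity and `L_mass` the age-weighted
larval biomass. The lethal transgene is a single dominant locus: carriers
of an affected sex halt in the egg (early acting) or the pupa (late
acting — after a full larval life of competing in the habitat). Mate
choice is weighted by male competitiveness `m`; the pool's *fecundity
potential*

    F = 1 − Σ m_i·[hom_i]/Σ m_i − Σ m_i·[het_i]/(2·Σ m_i)

tracks the chance a mating female produces wild-type female offspring.
A campaign burns in 180 days, takes a 30-day wild-type male baseline,
then releases `round(proportion × baseline)` homozygous males daily at
3 P.M. for a year; ten daily measures are recorded and normalized
against no-intervention control replicates. See `docs/methods.md` for
the full account.

## Worked example

```python
from sitsim import CampaignConfig, SITImplementation, run_experiment

cfg = CampaignConfig(
    implementation=SITImplementation.LFK,  # late-acting female-killing
    release_proportion=0.3,                # daily releases = 0.3 x baseline males
    released_competitiveness=1.0,
    campaign_days=180,
    replicates=5,
    master_seed=7,
)
result = run_experiment(cfg)
print("release number:", result.treated[0].release_number)
summary = result.suppression()
print("suppression factor:", round(summary.suppression_factor, 3))
print("elimination:", summary.elimination)
```

prints

```
release number: 156
suppression factor: 0.031
elimination: False
```

meaning the baseline census of ~521 wild-type adult males led to 156
released males per day, and after six months the wild-type adult female
population stands at 3.1% of the no-intervention control (not yet a full
30-day window of zero counts). The `result.normalized` frame holds all
ten measures day by day (`norm_i_wt_adult_females`,
`norm_v_fecundity_potential`, …).

Short narrative scripts in `examples/` cover each capability: lifecycle
rate curves, a single campaign, the onset lags of heterozygous cohorts,
and a release-proportion sweep. A thin CLI wraps the same library:

```bash
sitsim simulate --gene lbs --release-proportion 0.5 --seed 1 --out out/
sitsim sweep --genes lbs,lfk --proportions 0.3,0.7 --replicates 5 --out sweep/
```

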