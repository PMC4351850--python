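"""Single-locus dominant cell-lethal genetics, SIT implementations and mating.

The transgene is a single-locus, fully penetrant, dominant cell-lethal
allele. Released males are homozygous carriers; matings with wild females
therefore produce heterozygous offspring whose fate depends on the SIT
implementation:

* early acting (EBS, EFK) — carriers halt development in the egg and never
  enter the larval habitat;
* late acting (LBS, LFK) — carriers develop as normal larvae (contributing
  to density-dependent larval competition) and are removed at pupal exit;
* female killing (EFK, LFK) — only female carriers are affected, male
  carriers develop normally and can pass the allele on.

Mate choice is weighted by male mating competitiveness ``m`` (1.0 = wild
type); female competitiveness never affects her mating probability but is
averaged into her offspring's value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .lifecycle import LifeState, Sex

__all__ = [
    "Allele",
    "Zygosity",
    "Genotype",
    "SITImplementation",
    "Fate",
    "lethal_fate",
    "fate_codes",
    "offspring_allele_counts",
    "select_mate",
    "conceive_offspring",
    "WILD_TYPE",
    "HETEROZYGOUS",
    "HOMOZYGOUS",
]


class Allele(enum.IntEnum):
    WILD = 0
    LETHAL = 1


class Zygosity(enum.IntEnum):
    """Zygosity with respect to the lethal allele; the integer doubles as the
    lethal-allele count, and the indicator vector [wt, het, hom] follows the
    fecundity-potential convention."""

    WILD_TYPE = 0
    HETEROZYGOUS = 1
    HOMOZYGOUS = 2

    @property
    def indicator(self) -> tuple[int, int, int]:
        return tuple(int(i == self.value) for i in range(3))


@dataclass(frozen=True)
class Genotype:
    """Unordered allele pair at the single cell-lethal locus."""

    lethal_count: int  # 0, 1 or 2 copies of the lethal allele

    def __post_init__(self) -> None:
        if self.lethal_count not in (0, 1, 2):
            raise ValueError("lethal allele count must be 0, 1 or 2")

    @property
    def zygosity(self) -> Zygosity:
        return Zygosity(self.lethal_count)

    @property
    def alleles(self) -> frozenset | tuple:
        a = [Allele.LETHAL] * self.lethal_count + [Allele.WILD] * (2 - self.lethal_count)
        return tuple(a)

    @property
    def is_carrier(self) -> bool:
        return self.lethal_count > 0

    def draw_allele(self, rng: np.random.Generator) -> Allele:
        """One gamete allele, drawn uniformly from the pair."""
        return Allele.LETHAL if rng.random() < self.lethal_count / 2.0 else Allele.WILD


WILD_TYPE = Genotype(0)
HETEROZYGOUS = Genotype(1)
HOMOZYGOUS = Genotype(2)


class SITImplementation(str, enum.Enum):
    """The four transgenic SIT implementations (plus no intervention).

    Early/late decides the blocking stage (egg vs pupa); bisex/female-killing
    decides whether male carriers are affected.
    """

    NONE = "none"
    EBS = "ebs"  # early acting bisex
    EFK = "efk"  # early acting female killing
    LBS = "lbs"  # late acting bisex
    LFK = "lfk"  # late acting female killing

    @property
    def blocking_state(self) -> LifeState | None:
        if self in (SITImplementation.EBS, SITImplementation.EFK):
            return LifeState.EGG
        if self in (SITImplementation.LBS, SITImplementation.LFK):
            return LifeState.PUPA
        return None

    @property
    def female_only(self) -> bool:
        return self in (SITImplementation.EFK, SITImplementation.LFK)

    @property
    def affected_sexes(self) -> str:
        return "female_only" if self.female_only else ("both" if self is not SITImplementation.NONE else "none")


class Fate(enum.IntEnum):
    """Developmental fate of an agent, fixed at conception.

    The lethal gene is dominant and 100% penetrant: any carrier of an
    affected sex is blocked in the implementation's blocking state, where it
    is removed instead of developing further.
    """

    UNAFFECTED = 0
    BLOCKED_IN_EGG = 1
    BLOCKED_IN_PUPA = 2


def lethal_fate(genotype: Genotype, sex: Sex, implementation: SITImplementation) -> Fate:
    """Fate of one agent given its genotype, sex and the active implementation."""
    return Fate(int(fate_codes(np.array([genotype.lethal_count]), np.array([int(sex)]), implementation)[0]))


def fate_codes(lethal_counts: np.ndarray, sexes: np.ndarray, implementation: SITImplementation) -> np.ndarray:
    """Vectorized :func:`lethal_fate` over allele-count and sex arrays."""
    out = np.zeros(len(lethal_counts), dtype=np.int8)
    block = implementation.blocking_state
    if block is None:
        return out
    affected = np.asarray(lethal_counts) > 0
    if implementation.female_only:
        affected = affected & (np.asarray(sexes) == int(Sex.FEMALE))
    code = Fate.BLOCKED_IN_EGG if block is LifeState.EGG else Fate.BLOCKED_IN_PUPA
    out[affected] = int(code)
    return out


def offspring_allele_counts(
    mother_counts: np.ndarray, sire_counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mendelian inheritance at the lethal locus, one offspring per entry.

    Each parent contributes one allele drawn uniformly from its pair, i.e. a
    lethal allele with probability (parental lethal count)/2.
    """
    m = rng.random(len(mother_counts)) < np.asarray(mother_counts) / 2.0
    s = rng.random(len(sire_counts)) < np.asarray(sire_counts) / 2.0
    return (m.astype(np.int8) + s.astype(np.int8)).astype(np.int8)


def select_mate(female, males, rng: np.random.Generator):
    """Choose a mate for ``female`` from the mate-seeking ``males``.

    Sampling is weighted by each male's competitiveness ``m_i`` (probability
    ``m_i / sum m_j``); the female's own competitiveness plays no role. The
    female's sire record is set and she leaves mate seeking; the chosen male
    remains mate seeking. Returns the chosen male, or None when the pool is
    empty or carries zero total weight (the female simply waits for a later
    mating hour).
    """
    males = list(males)
    if not males:
        return None
    w = np.array([m.competitiveness for m in males], dtype=float)
    total = w.sum()
    if total <= 0:
        return None
    mate = males[int(rng.choice(len(males), p=w / total))]
    female.sire_genotype = mate.genotype
    female.sire_competitiveness = mate.competitiveness
    female.state = LifeState.BLOODMEAL_SEEKING
    return mate


def conceive_offspring(mother, count: int, rng: np.random.Generator, implementation=SITImplementation.NONE):
    """Create ``count`` new egg agents from a mated mother.

    Each egg independently gets a fair-coin sex, one allele from each parent,
    the parental mean competitiveness, and a cached developmental fate.
    """
    from .population import MosquitoAgent  # local import to avoid a cycle

    if mother.sire_genotype is None:
        raise ValueError("mother has no sire record; females must mate before laying")
    if count <= 0:
        raise ValueError("count must be positive")
    mc = np.full(count, mother.genotype.lethal_count)
    sc = np.full(count, mother.sire_genotype.lethal_count)
    counts = offspring_allele_counts(mc, sc, rng)
    sexes = rng.integers(0, 2, size=count)
    comp = (mother.competitiveness + mother.sire_competitiveness) / 2.0
    eggs = []
    for sex, cnt in zip(sexes, counts):
        g = Genotype(int(cnt))
        eggs.append(
            MosquitoAgent(
                sex=Sex(int(sex)),
                genotype=g,
                competitiveness=comp,
                state=LifeState.EGG,
                fate=lethal_fate(g, Sex(int(sex)), implementation),
            )
        )
    return eggs
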