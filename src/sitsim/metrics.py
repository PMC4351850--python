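"""The ten daily output measures, normalization and suppression summaries.

Every simulated campaign day the engine records, at the census hour
(15:00, immediately before that day's release):

====  =========================================  ==========================
 i    wild-type adult females                    suppression endpoint
 ii   wild-type adult males
 iii  homozygous adult males                     the released males
 iv   heterozygous adult males                   the carrier reservoir
 v    fecundity potential F                      computed *after* release
 vi   wild-type larval females
 vii  wild-type larval males
 viii heterozygous larval females
 ix   heterozygous larval males
 x    larval mortality factor L_mass / C
====  =========================================  ==========================

Treated series are normalized by dividing each day's value by the
across-replicate mean of the matching control (no-intervention) output;
population measures are normalized with the control's *wild-type* numbers
(controls contain no transgenics). The suppression factor is the mean
normalized wild-type adult female count over a final window (default the
last 30 days): 0 = elimination, 1 = no effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import SITImplementation
from .population import LarvalHabitat, larval_biomass

__all__ = [
    "RAW_COLUMNS",
    "NORM_SOURCE",
    "MeasureSeries",
    "SuppressionSummary",
    "fecundity_potential",
    "larval_mortality_factor",
    "census_row",
    "normalize",
    "suppression_factor",
]

#: Raw per-day measure columns, in the i..x order.
RAW_COLUMNS = [
    "raw_i_wt_adult_females",
    "raw_ii_wt_adult_males",
    "raw_iii_homo_adult_males",
    "raw_iv_het_adult_males",
    "raw_v_fecundity_potential",
    "raw_vi_wt_larval_females",
    "raw_vii_wt_larval_males",
    "raw_viii_het_larval_females",
    "raw_ix_het_larval_males",
    "raw_x_larval_mortality_factor",
]

#: Extra raw columns logged for verification only (not among the measures).
EXTRA_COLUMNS = ["raw_homo_larval_females", "raw_homo_larval_males"]

#: Which *control* column each measure is normalized against. Transgenic
#: population classes are normalized with the control's wild-type numbers.
NORM_SOURCE = {
    "raw_i_wt_adult_females": "raw_i_wt_adult_females",
    "raw_ii_wt_adult_males": "raw_ii_wt_adult_males",
    "raw_iii_homo_adult_males": "raw_ii_wt_adult_males",
    "raw_iv_het_adult_males": "raw_ii_wt_adult_males",
    "raw_v_fecundity_potential": "raw_v_fecundity_potential",
    "raw_vi_wt_larval_females": "raw_vi_wt_larval_females",
    "raw_vii_wt_larval_males": "raw_vii_wt_larval_males",
    "raw_viii_het_larval_females": "raw_vi_wt_larval_females",
    "raw_ix_het_larval_males": "raw_vii_wt_larval_males",
    "raw_x_larval_mortality_factor": "raw_x_larval_mortality_factor",
}

#: A MeasureSeries is a DataFrame indexed by campaign day (0 = first release
#: day) with the RAW_COLUMNS above, plus norm_ columns once normalized.
MeasureSeries = pd.DataFrame


@dataclass(frozen=True)
class SuppressionSummary:
    """End-of-campaign suppression for one (gene, proportion, m) cell."""

    implementation: SITImplementation
    release_proportion: float
    competitiveness: float
    suppression_factor: float
    elimination: bool
    final_window_days: int = 30


def fecundity_potential(lethal_counts, comps) -> float:
    """Fecundity potential F of a mate-seeking male pool.

    ``F = 1 - sum(m_i [hom_i]) / sum(m_i) - sum(m_i [het_i]) / (2 sum(m_i))``

    i.e. one minus the competitiveness-weighted share of matings expected to
    yield lethal-carrying female offspring; homozygous sires pass the allele
    to every offspring, heterozygous sires to half. Returns NaN for an empty
    pool or a pool with zero total competitiveness (the statistic is
    undefined there; downstream averaging skips missing days).
    """
    z = np.asarray(lethal_counts)
    m = np.asarray(comps, dtype=float)
    if z.size == 0:
        return float("nan")
    total = m.sum()
    if total <= 0:
        return float("nan")
    hom = m[z == 2].sum()
    het = m[z == 1].sum()
    return float(1.0 - hom / total - het / (2.0 * total))


def larval_mortality_factor(habitat: LarvalHabitat, hour: int | None = None) -> float:
    """The density-dependence driver L_mass / C at the census hour."""
    return larval_biomass(habitat, hour) / habitat.carrying_capacity


def census_row(pop) -> dict:
    """Raw measures i-iv and vi-x from the live population (F is appended by
    the campaign driver after the release event)."""
    from .lifecycle import Sex

    return {
        "raw_i_wt_adult_females": pop.adult_count(sex=Sex.FEMALE, alleles=0),
        "raw_ii_wt_adult_males": pop.adult_count(sex=Sex.MALE, alleles=0),
        "raw_iii_homo_adult_males": pop.adult_count(sex=Sex.MALE, alleles=2),
        "raw_iv_het_adult_males": pop.adult_count(sex=Sex.MALE, alleles=1),
        "raw_vi_wt_larval_females": pop.larva_count(sex=Sex.FEMALE, alleles=0),
        "raw_vii_wt_larval_males": pop.larva_count(sex=Sex.MALE, alleles=0),
        "raw_viii_het_larval_females": pop.larva_count(sex=Sex.FEMALE, alleles=1),
        "raw_ix_het_larval_males": pop.larva_count(sex=Sex.MALE, alleles=1),
        "raw_x_larval_mortality_factor": larval_mortality_factor(pop.habitat),
        "raw_homo_larval_females": pop.larva_count(sex=Sex.FEMALE, alleles=2),
        "raw_homo_larval_males": pop.larva_count(sex=Sex.MALE, alleles=2),
    }


def normalize(series: MeasureSeries, control: MeasureSeries) -> MeasureSeries:
    """Attach norm_ columns: each measure divided, day by day, by the control
    run's corresponding wild-type (or same-measure) value.

    Division by a zero control value yields a missing (NaN) entry. The day
    grids must match.
    """
    if not series.index.equals(control.index):
        raise ValueError("treated and control series must share the same day grid")
    out = series.copy()
    for col, src in NORM_SOURCE.items():
        denom = control[src].astype(float).replace(0.0, np.nan)
        out[col.replace("raw_", "norm_")] = series[col].astype(float) / denom
    return out


def suppression_factor(
    treated: MeasureSeries,
    control: MeasureSeries,
    window_days: int = 30,
    implementation: SITImplementation = SITImplementation.NONE,
    release_proportion: float = 0.0,
    competitiveness: float = 1.0,
) -> SuppressionSummary:
    """Final-window suppression of the wild-type adult female population.

    The factor is the mean control-normalized wild-type adult female count
    over the last ``window_days`` days; the elimination flag is set when the
    raw treated mean over that window is exactly zero.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    if len(treated) < window_days or len(control) < window_days:
        raise ValueError("final window longer than the recorded series")
    t = treated["raw_i_wt_adult_females"].to_numpy(dtype=float)[-window_days:]
    c = control["raw_i_wt_adult_females"].to_numpy(dtype=float)[-window_days:]
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(c > 0, t / np.where(c > 0, c, 1.0), np.nan)
    factor = float(np.nanmean(norm)) if np.any(np.isfinite(norm)) else float("nan")
    return SuppressionSummary(
        implementation=SITImplementation(implementation),
        release_proportion=float(release_proportion),
        competitiveness=float(competitiveness),
        suppression_factor=factor,
        elimination=bool(t.mean() == 0.0),
        final_window_days=int(window_days),
    )
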