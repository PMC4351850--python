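"""Fixture populations and sweep orchestration over the experiment grid."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .campaign import (
    CampaignConfig,
    ReplicateResult,
    _mean_measures,
    run_arm,
)
from .genetics import SITImplementation, WILD_TYPE
from .lifecycle import LifeState, Sex
from .metrics import suppression_factor
from .population import MosquitoAgent

__all__ = ["SweepSpec", "generate_fixture_population", "run_sweep"]


def generate_fixture_population(n_adults: int, seed: int = 0, rng=None) -> list[MosquitoAgent]:
    """A deterministic small wild-type adult population.

    Exactly half females, half males (``n_adults`` must be even and >= 2),
    all wild type with competitiveness 1.0, ages staggered over 0-9 days.
    Males are mate seeking; females are already mated to a wild-type sire
    and are mid-gonotrophic-cycle (bloodmeal seeking), so a seeded burn-in
    produces eggs from the first night. The construction is deterministic:
    ``seed``/``rng`` are accepted for interface symmetry but unused.
    """
    if n_adults < 2:
        raise ValueError("need at least 2 adults")
    if n_adults % 2:
        raise ValueError("n_adults must be even (1:1 sex ratio)")
    agents = []
    for i in range(n_adults):
        female = i % 2 == 0
        agents.append(
            MosquitoAgent(
                sex=Sex.FEMALE if female else Sex.MALE,
                genotype=WILD_TYPE,
                competitiveness=1.0,
                state=LifeState.BLOODMEAL_SEEKING if female else LifeState.MATE_SEEKING,
                age_days=float((i * 7) % 10),
                sire_genotype=WILD_TYPE if female else None,
                sire_competitiveness=1.0 if female else None,
            )
        )
    return agents


@dataclass(frozen=True)
class SweepSpec:
    """Cartesian experiment grid: gene x release proportion x competitiveness.

    Every cell runs ``replicates`` treated replicates; a single shared
    control arm (identical non-SIT settings) provides the normalization for
    all cells.
    """

    implementations: tuple = (
        SITImplementation.EBS,
        SITImplementation.EFK,
        SITImplementation.LBS,
        SITImplementation.LFK,
    )
    proportions: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    competitiveness_levels: tuple = (1.0, 0.75, 0.5)
    replicates: int = 10

    def cells(self):
        return list(product(self.implementations, self.proportions, self.competitiveness_levels))


def _cell_summary(
    cell_index: int,
    impl: SITImplementation,
    prop: float,
    comp: float,
    base: CampaignConfig,
    spec: SweepSpec,
    control_mean,
) -> dict:
    config = replace(
        base,
        implementation=SITImplementation(impl),
        release_proportion=float(prop),
        released_competitiveness=float(comp),
        replicates=spec.replicates,
    )
    treated = run_arm(config, arm_key=(0, cell_index))
    failed = any(r.failed_calibration for r in treated)
    treated_mean = _mean_measures(treated)
    summary = suppression_factor(
        treated_mean,
        control_mean,
        min(config.final_window_days, len(treated_mean)),
        implementation=config.implementation,
        release_proportion=prop,
        competitiveness=comp,
    )
    return {
        "implementation": SITImplementation(impl).value,
        "release_proportion": float(prop),
        "competitiveness": float(comp),
        "suppression_factor": summary.suppression_factor,
        "elimination": summary.elimination,
        "failed_calibration": failed,
        "release_number": treated[0].release_number,
    }


def run_sweep(
    spec: SweepSpec,
    base_config: CampaignConfig,
    cache_dir: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full grid and return one suppression-summary row per cell.

    The control arm is run once and shared across every cell (all cells have
    identical non-SIT settings). With ``cache_dir`` set, each completed cell
    is written to disk and re-used on resume, so an interrupted sweep picks
    up where it left off and produces the identical grid.
    """
    control = run_arm(base_config.control, arm_key=(1,), replicates=spec.replicates)
    control_mean = _mean_measures(control)
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, (impl, prop, comp) in enumerate(spec.cells()):
        cell_file = (
            cache / f"cell_{SITImplementation(impl).value}_p{prop:g}_m{comp:g}.json" if cache is not None else None
        )
        if cell_file is not None and cell_file.exists():
            rows.append(json.loads(cell_file.read_text()))
            continue
        row = _cell_summary(ci, impl, prop, comp, base_config, spec, control_mean)
        if cell_file is not None:
            cell_file.write_text(json.dumps(row))
        rows.append(row)
        if progress:
            print(
                f"[{ci + 1}/{len(spec.cells())}] {row['implementation']} p={prop:g} m={comp:g}: "
                f"suppression {row['suppression_factor']:.3f}",
                flush=True,
            )
    return pd.DataFrame(rows)
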