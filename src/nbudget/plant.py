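"""Plant nitrogen accumulation and seasonal yield aggregates.

Organ N accumulation (kg·ha⁻¹) is N content (%) × dry matter (kg·ha⁻¹);
whole-plant accumulation sums leaves and stems; a season summary sums
over cuts and reports hay yield as total leaf + stem dry matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import DataError, PlotObservationKey, ValidationError


@dataclass(frozen=True)
class PlantCutSample:
    """One cut's leaf/stem N contents (%) and dry matter (kg·ha⁻¹)."""

    leaf_n: float
    stem_n: float
    leaf_dm: float
    stem_dm: float
    key: PlotObservationKey | None = None

    def __post_init__(self) -> None:
        for name, v in (("leaf_n", self.leaf_n), ("stem_n", self.stem_n)):
            if not 0 <= v <= 100:
                raise ValidationError(f"{name} must be a percent in [0, 100], got {v}")
        if self.leaf_dm < 0 or self.stem_dm < 0:
            raise ValidationError("dry matter must be >= 0")


@dataclass(frozen=True)
class SeasonPlantSummary:
    """Season totals for one plot-year."""

    plant_n_accumulation: float  # kg N·ha⁻¹
    hay_yield: float  # kg·ha⁻¹ dry matter
    n_cuts: int


def organ_accumulation(n_pct: float, dm: float) -> float:
    """N accumulation of one organ: content (%) × dry matter / 100."""
    if not 0 <= n_pct <= 100:
        raise ValidationError(f"N content must be a percent in [0, 100], got {n_pct}")
    if dm < 0:
        raise ValidationError(f"dry matter must be >= 0, got {dm}")
    return n_pct / 100.0 * dm


def plant_accumulation(sample: PlantCutSample) -> float:
    """Whole-plant N accumulation for one cut: leaves + stems."""
    return (organ_accumulation(sample.leaf_n, sample.leaf_dm)
            + organ_accumulation(sample.stem_n, sample.stem_dm))


def season_summary(samples: Sequence[PlantCutSample]) -> SeasonPlantSummary:
    """Sum cuts of one plot-year into seasonal N accumulation and hay yield.

    Cut indices (when keyed) must be distinct; order is irrelevant.
    """
    if not samples:
        raise DataError("season_summary needs at least one cut sample")
    cuts = [s.key.cut for s in samples if s.key is not None and s.key.cut is not None]
    if len(cuts) != len(set(cuts)):
        raise DataError(f"duplicate cut index in season samples: {sorted(cuts)}")
    acc = sum(plant_accumulation(s) for s in samples)
    dm = sum(s.leaf_dm + s.stem_dm for s in samples)
    return SeasonPlantSummary(plant_n_accumulation=acc, hay_yield=dm, n_cuts=len(samples))


def summary_table(plant: pd.DataFrame) -> pd.DataFrame:
    """Per-plot-year season summaries from a validated ``plant`` table.

    Returns one row per (year, pattern, n_rate, replicate) with
    ``plant_n_kg_ha``, ``hay_yield_kg_ha`` and ``n_cuts``.
    """
    keys = ["year", "pattern", "n_rate", "replicate"]
    dup = plant.duplicated(subset=keys + ["cut"])
    if dup.any():
        row = plant[dup].iloc[0]
        raise DataError(
            f"duplicate cut {int(row['cut'])} for plot "
            f"{row['year']}/{row['pattern']}/{row['n_rate']}/rep {int(row['replicate'])}"
        )
    acc = (plant["leaf_n_pct"] / 100.0 * plant["leaf_dm_kg_ha"]
           + plant["stem_n_pct"] / 100.0 * plant["stem_dm_kg_ha"])
    dm = plant["leaf_dm_kg_ha"] + plant["stem_dm_kg_ha"]
    out = (
        plant.assign(plant_n_kg_ha=acc, hay_yield_kg_ha=dm)
        .groupby(keys, sort=True)
        .agg(plant_n_kg_ha=("plant_n_kg_ha", "sum"),
             hay_yield_kg_ha=("hay_yield_kg_ha", "sum"),
             n_cuts=("cut", "nunique"))
        .reset_index()
    )
    return out
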