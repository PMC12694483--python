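"""Soil inorganic-nitrogen stocks.

A layer's stock (kg N·ha⁻¹) is ``γ·h·N / 10`` with bulk density γ in
g·cm⁻³, thickness h in cm and concentration N in mg·kg⁻¹; the divisor 10
is the exact unit conversion (1 g·cm⁻³ × 1 cm × 1 mg·kg⁻¹ = 0.1 kg·ha⁻¹).
Profile stocks sum contiguous layers, conventionally 0–60 cm in three
20 cm intervals; the inorganic-N reserve is the NO₃⁻-N plus NH₄⁺-N
profile stock.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .core import DataError, PlotObservationKey, ValidationError

#: Site default dry bulk density (g·cm⁻³), used when a layer omits its own.
DEFAULT_BULK_DENSITY = 1.45


class NSpecies(str, enum.Enum):
    NO3 = "NO3"
    NH4 = "NH4"


@dataclass(frozen=True)
class SoilLayerObservation:
    """One depth interval: bulk density and inorganic-N concentrations."""

    depth_top: float  # cm
    depth_bottom: float  # cm
    no3: float  # mg·kg⁻¹
    nh4: float  # mg·kg⁻¹
    bulk_density: float = DEFAULT_BULK_DENSITY  # g·cm⁻³

    def __post_init__(self) -> None:
        if self.depth_bottom <= self.depth_top:
            raise ValidationError(
                f"depth_bottom ({self.depth_bottom}) must exceed "
                f"depth_top ({self.depth_top})"
            )
        if self.bulk_density <= 0:
            raise ValidationError(f"bulk density must be > 0, got {self.bulk_density}")
        if self.no3 < 0 or self.nh4 < 0:
            raise ValidationError("concentrations must be >= 0")

    @property
    def thickness(self) -> float:
        """Layer thickness h (cm)."""
        return self.depth_bottom - self.depth_top

    def concentration(self, species: NSpecies) -> float:
        return {NSpecies.NO3: self.no3, NSpecies.NH4: self.nh4}[NSpecies(species)]


@dataclass(frozen=True)
class SoilProfile:
    """An ordered, contiguous stack of layers for one plot sampling."""

    layers: tuple[SoilLayerObservation, ...]
    key: PlotObservationKey | None = None

    def __post_init__(self) -> None:
        layers = tuple(sorted(self.layers, key=lambda la: la.depth_top))
        if not layers:
            raise ValidationError("profile needs at least one layer")
        for upper, lower in zip(layers, layers[1:]):
            if lower.depth_top != upper.depth_bottom:
                kind = "gap" if lower.depth_top > upper.depth_bottom else "overlap"
                raise DataError(
                    f"{kind} between layers at {upper.depth_bottom} and "
                    f"{lower.depth_top} cm"
                )
        object.__setattr__(self, "layers", layers)


def layer_stock(layer: SoilLayerObservation, species: NSpecies) -> float:
    """Stock of one species in one layer, kg N·ha⁻¹: γ·h·N/10."""
    return layer.bulk_density * layer.thickness * layer.concentration(species) / 10.0


def profile_stock(profile: SoilProfile, species: NSpecies) -> float:
    """Stock of one species over the whole profile (sum of layers)."""
    return sum(layer_stock(layer, species) for layer in profile.layers)


def inorganic_n_reserve(profile: SoilProfile) -> float:
    """Total inorganic-N reserve: NO₃⁻-N + NH₄⁺-N profile stocks."""
    return profile_stock(profile, NSpecies.NO3) + profile_stock(profile, NSpecies.NH4)


def profiles_from_table(soil: pd.DataFrame) -> Iterable[tuple[tuple, SoilProfile]]:
    """Group a validated ``soil`` schema table into per-plot-date profiles.

    Yields ``((year, pattern, n_rate, replicate, date), SoilProfile)`` in
    sorted key order.
    """
    keys = ["year", "pattern", "n_rate", "replicate", "date"]
    for key, grp in soil.groupby(keys, sort=True):
        layers = tuple(
            SoilLayerObservation(
                depth_top=row.depth_top_cm,
                depth_bottom=row.depth_bottom_cm,
                no3=row.no3_mg_kg,
                nh4=row.nh4_mg_kg,
                bulk_density=row.bulk_density_g_cm3,
            )
            for row in grp.itertuples()
        )
        yield key, SoilProfile(layers)


def stock_table(soil: pd.DataFrame) -> pd.DataFrame:
    """Per-plot-date profile stocks from a validated ``soil`` table.

    Returns one row per (year, pattern, n_rate, replicate, date) with
    ``no3_stock_kg_ha``, ``nh4_stock_kg_ha`` and ``inorganic_n_kg_ha``.
    """
    rows = []
    for key, profile in profiles_from_table(soil):
        no3 = profile_stock(profile, NSpecies.NO3)
        nh4 = profile_stock(profile, NSpecies.NH4)
        rows.append(key + (no3, nh4, no3 + nh4))
    return pd.DataFrame(
        rows,
        columns=[
            "year", "pattern", "n_rate", "replicate", "date",
            "no3_stock_kg_ha", "nh4_stock_kg_ha", "inorganic_n_kg_ha",
        ],
    )
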