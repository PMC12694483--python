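"""Shared domain types, unit conventions and reporting policy.

Conventions used throughout the package:

* masses per hectare (kg·ha⁻¹), concentrations in mg·kg⁻¹ dry soil,
* nitrogen contents stored as percent (3.0 means 3 %), converted to
  fractions only inside computations,
* the canonical N₂O flux unit is µg N₂O-N·m⁻²·h⁻¹; reporting may convert
  to mg·m⁻²·h⁻¹ (an exact power of ten),
* dates are ISO calendar dates; intervals are whole-day differences,
* report tables round half-away-from-zero to a configurable number of
  decimals (default 2); internal computation never rounds.
"""

from __future__ import annotations

import decimal
import enum
from dataclasses import dataclass, field
from datetime import date
from typing import Optional


class NbudgetError(Exception):
    """Base class for all package errors."""


class ValidationError(NbudgetError):
    """A value violates a type invariant (e.g. negative bulk density)."""


class SchemaError(NbudgetError):
    """A table does not match its declared schema."""


class DataError(NbudgetError):
    """Structurally valid data that cannot be processed (duplicates, gaps...)."""


class DesignError(NbudgetError):
    """A statistical design is degenerate (no error df, one level...)."""


class Pattern(str, enum.Enum):
    """Cropping pattern: flat planting, ridge + biodegradable mulch,
    ridge + conventional plastic mulch."""

    FP = "FP"
    JM = "JM"
    PM = "PM"


#: Conventional level codes for the default nitrogen rates (kg N·ha⁻¹).
RATE_LEVELS = {0.0: "C0", 80.0: "C1", 160.0: "C2", 240.0: "C3"}


@dataclass(frozen=True, order=True)
class Treatment:
    """A (cropping pattern, nitrogen rate) treatment cell.

    ``n_rate`` is the fertilizer application in kg N·ha⁻¹; any non-negative
    value is allowed, with 0/80/160/240 as the conventional levels C0–C3.
    """

    pattern: Pattern
    n_rate: float

    def __post_init__(self) -> None:
        if self.n_rate < 0:
            raise ValidationError(f"n_rate must be >= 0, got {self.n_rate}")
        object.__setattr__(self, "pattern", Pattern(self.pattern))

    @property
    def label(self) -> str:
        """Conventional label, e.g. ``PMC2``; falls back to ``PM-100`` for
        off-grid rates."""
        level = RATE_LEVELS.get(float(self.n_rate))
        if level is None:
            return f"{self.pattern.value}-{self.n_rate:g}"
        return f"{self.pattern.value}{level}"


@dataclass(frozen=True)
class PlotObservationKey:
    """Identifies one plot-level observation: year, treatment, replicate,
    optional cut index (plant samples only) and calendar date."""

    year: int
    treatment: Treatment
    replicate: int
    date: Optional[date] = None
    cut: Optional[int] = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.cut is not None and self.cut < 1:
            raise ValidationError(f"cut must be >= 1, got {self.cut}")


class FluxUnit(str, enum.Enum):
    UG_M2_H = "ug_m2_h"
    MG_M2_H = "mg_m2_h"


#: Exact power-of-ten factors to the canonical µg·m⁻²·h⁻¹.
_TO_UG = {FluxUnit.UG_M2_H: 1.0, FluxUnit.MG_M2_H: 1e3}


def convert_flux(value: float, src: FluxUnit, dst: FluxUnit) -> float:
    """Convert a flux between µg and mg·m⁻²·h⁻¹ (exact powers of ten)."""
    return value * _TO_UG[FluxUnit(src)] / _TO_UG[FluxUnit(dst)]


@dataclass(frozen=True)
class UnitPolicy:
    """Reporting policy: flux unit for tables and decimal places for
    rounded report values (half away from zero)."""

    flux_unit: FluxUnit = FluxUnit.UG_M2_H
    decimals: int = 2


DEFAULT_POLICY = UnitPolicy()


def round_report(x: float, policy: UnitPolicy = DEFAULT_POLICY) -> float:
    """Round ``x`` for a report table: half away from zero, ``policy.decimals``
    places. Internal computations never pass through here."""
    if not _is_finite(x):
        raise ValidationError(f"cannot round non-finite value {x!r}")
    q = decimal.Decimal(10) ** -policy.decimals
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def _is_finite(x: float) -> bool:
    try:
        return x == x and x not in (float("inf"), float("-inf"))
    except TypeError:
        return False
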