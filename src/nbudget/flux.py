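"""Static-chamber N₂O flux and seasonal cumulative emission.

The closed-chamber flux is

    F = ρ · H · (dc/dt) · 273/(273 + T) · 60

with ρ = 2×14/22.4 = 1.25 kg·m⁻³ (N₂O-N basis: 28 g N per mole of N₂O at
standard conditions), chamber height H in m, headspace concentration
slope dc/dt in µL·L⁻¹·min⁻¹ and mean chamber air temperature T in °C.
The product of that expression is in mg N₂O-N·m⁻²·h⁻¹ and is converted
to the canonical µg·m⁻²·h⁻¹ internally.

Ridge–furrow plots carry two chambers; their fluxes combine as an
area-weighted average. Seasonal totals integrate dated fluxes with the
trapezoidal rule,

    f = Σ (Fᵢ₊₁ + Fᵢ)/2 · tᵢ · 24 · 10⁻⁵   (kg·ha⁻¹),

tᵢ the whole-day gap between consecutive campaigns; 24·10⁻⁵ converts
µg·m⁻²·h⁻¹ × days to kg·ha⁻¹. No extrapolation happens outside the first
and last sampling dates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DataError, PlotObservationKey, UnitPolicy, DEFAULT_POLICY, ValidationError

#: N₂O-N density at standard conditions, kg·m⁻³ (2 × 14 g / 22.4 L).
RHO_N2O_N = 2 * 14 / 22.4

#: (µg·m⁻²·h⁻¹ × day) → kg·ha⁻¹ in the trapezoid sum.
DAY_TO_KG_HA = 24e-5

#: Chambers with at least this many points and a poorer linear fit are
#: flagged (never dropped).
R2_FLAG_THRESHOLD = 0.90


class Position(str, enum.Enum):
    FLAT = "flat"
    RIDGE = "ridge"
    FURROW = "furrow"


@dataclass(frozen=True)
class ChamberSeries:
    """One chamber deployment: timed headspace concentrations plus the
    chamber geometry and mean temperature needed for the flux formula."""

    minutes: tuple[float, ...]
    conc: tuple[float, ...]  # µL·L⁻¹
    height: float  # m
    temp: float  # °C
    position: Position = Position.FLAT
    key: PlotObservationKey | None = None

    def __post_init__(self) -> None:
        if len(self.minutes) != len(self.conc):
            raise ValidationError("minutes and conc must have equal length")
        if len(self.minutes) < 2:
            raise DataError("a chamber series needs at least 2 samples")
        if any(b <= a for a, b in zip(self.minutes, self.minutes[1:])):
            raise DataError("sampling minutes must be strictly increasing")
        if self.height <= 0:
            raise ValidationError(f"chamber height must be > 0, got {self.height}")
        if self.temp <= -273:
            raise ValidationError(f"temperature must exceed -273 degC, got {self.temp}")


@dataclass(frozen=True)
class FluxRecord:
    """One dated flux estimate with its slope-fit diagnostics."""

    flux: float  # µg N₂O-N·m⁻²·h⁻¹; negative = uptake
    r_squared: float  # NaN when the fit is degenerate (zero variance)
    n_points: int
    date: date | None = None
    key: PlotObservationKey | None = None

    @property
    def flagged(self) -> bool:
        """Quality flag: ≥3 points but r² below the linearity threshold."""
        return (self.n_points >= 3 and not math.isnan(self.r_squared)
                and self.r_squared < R2_FLAG_THRESHOLD)


@dataclass(frozen=True)
class SeasonEmission:
    """Seasonal cumulative N₂O-N emission for one plot-year."""

    total: float  # kg·ha⁻¹
    n_records: int
    first: date | None = None
    last: date | None = None


def concentration_slope(series: ChamberSeries) -> tuple[float, float, int]:
    """OLS slope of concentration vs time.

    Returns ``(slope µL·L⁻¹·min⁻¹, r², n)``. r² is 1.0 for a two-point
    series and NaN when the concentrations have zero variance (the slope
    is then 0 by construction).
    """
    x = np.asarray(series.minutes, dtype=float)
    y = np.asarray(series.conc, dtype=float)
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    if sxx == 0:  # unreachable given strictly increasing minutes; belt and braces
        raise DataError("degenerate design: all sampling minutes equal")
    if np.ptp(y) == 0:  # constant concentration: slope 0, r2 undefined
        return 0.0, float("nan"), n
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    if n == 2:
        return slope, 1.0, n
    resid = y - (y.mean() + slope * (x - x.mean()))
    r2 = float(1.0 - np.sum(resid ** 2) / syy)
    return slope, r2, n


def flux_from_slope(slope: float, height: float, temp: float) -> float:
    """Chamber flux in µg N₂O-N·m⁻²·h⁻¹ from a headspace slope."""
    if temp <= -273:
        raise ValidationError(f"temperature must exceed -273 degC, got {temp}")
    mg_m2_h = RHO_N2O_N * height * slope * (273.0 / (273.0 + temp)) * 60.0
    return mg_m2_h * 1e3


def flux(series: ChamberSeries, policy: UnitPolicy = DEFAULT_POLICY) -> FluxRecord:
    """Estimate one chamber's flux; negative slopes give negative flux."""
    slope, r2, n = concentration_slope(series)
    f = flux_from_slope(slope, series.height, series.temp)
    d = series.key.date if series.key is not None else None
    return FluxRecord(flux=f, r_squared=r2, n_points=n, date=d, key=series.key)


def position_weighted_flux(ridge: FluxRecord, furrow: FluxRecord,
                           w_ridge: float = 0.5) -> FluxRecord:
    """Area-weighted plot flux from paired ridge and furrow chambers."""
    if not 0 <= w_ridge <= 1:
        raise ValidationError(f"w_ridge must lie in [0, 1], got {w_ridge}")
    if ridge.key != furrow.key or ridge.date != furrow.date:
        raise DataError("ridge and furrow records must share key and date")
    f = w_ridge * ridge.flux + (1 - w_ridge) * furrow.flux
    r2 = min(ridge.r_squared, furrow.r_squared)
    return FluxRecord(flux=f, r_squared=r2,
                      n_points=min(ridge.n_points, furrow.n_points),
                      date=ridge.date, key=ridge.key)


def cumulative_emission(records: Sequence[FluxRecord],
                        policy: UnitPolicy = DEFAULT_POLICY) -> SeasonEmission:
    """Trapezoidal seasonal total over dated flux records, kg·ha⁻¹."""
    if len(records) < 2:
        raise DataError("cumulative emission needs at least 2 dated records")
    if any(r.date is None for r in records):
        raise DataError("every flux record needs a date")
    recs = sorted(records, key=lambda r: r.date)
    dates = [r.date for r in recs]
    if any(b == a for a, b in zip(dates, dates[1:])):
        raise DataError(f"duplicate flux dates: {dates}")
    total = 0.0
    for a, b in zip(recs, recs[1:]):
        t_days = (b.date - a.date).days
        total += (a.flux + b.flux) / 2.0 * t_days * DAY_TO_KG_HA
    return SeasonEmission(total=total, n_records=len(recs),
                          first=dates[0], last=dates[-1])


# ---------------------------------------------------------------------------
# table-level drivers

def flux_table(chamber: pd.DataFrame, w_ridge: float = 0.5) -> pd.DataFrame:
    """Per-plot-date fluxes from a validated ``chamber`` table.

    Ridge and furrow chambers of the same plot-date are combined by area
    weighting; flat chambers pass through. Returns a ``flux``-schema frame.
    """
    keys = ["year", "pattern", "n_rate", "replicate", "date"]
    rows = []
    for key, grp in chamber.groupby(keys, sort=True):
        by_pos: dict[str, FluxRecord] = {}
        for pos, sub in grp.groupby("position"):
            sub = sub.sort_values("minute")
            series = ChamberSeries(
                minutes=tuple(sub["minute"]), conc=tuple(sub["conc_ul_l"]),
                height=float(sub["height_m"].iloc[0]),
                temp=float(sub["temp_c"].mean()),
                position=Position(pos),
            )
            slope, r2, n = concentration_slope(series)
            by_pos[pos] = FluxRecord(
                flux=flux_from_slope(slope, series.height, series.temp),
                r_squared=r2, n_points=n, date=key[4],
            )
        if "flat" in by_pos:
            rec = by_pos["flat"]
        elif {"ridge", "furrow"} <= by_pos.keys():
            rec = FluxRecord(
                flux=w_ridge * by_pos["ridge"].flux + (1 - w_ridge) * by_pos["furrow"].flux,
                r_squared=min(by_pos["ridge"].r_squared, by_pos["furrow"].r_squared),
                n_points=min(by_pos["ridge"].n_points, by_pos["furrow"].n_points),
                date=key[4],
            )
        else:
            raise DataError(
                f"plot {key}: need a flat chamber or a ridge+furrow pair, "
                f"got positions {sorted(by_pos)}"
            )
        rows.append(key + (rec.flux, rec.r_squared, rec.n_points))
    return pd.DataFrame(rows, columns=keys + ["flux_ug_m2_h", "r_squared", "n_points"])


def emission_table(flux_df: pd.DataFrame) -> pd.DataFrame:
    """Per-plot-year seasonal emissions from a validated ``flux`` table."""
    keys = ["year", "pattern", "n_rate", "replicate"]
    rows = []
    for key, grp in flux_df.groupby(keys, sort=True):
        recs = [
            FluxRecord(flux=r.flux_ug_m2_h, r_squared=r.r_squared,
                       n_points=int(r.n_points), date=r.date)
            for r in grp.itertuples()
        ]
        em = cumulative_emission(recs)
        rows.append(key + (em.total, em.n_records))
    return pd.DataFrame(rows, columns=keys + ["n2o_emission_kg_ha", "n_campaigns"])
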