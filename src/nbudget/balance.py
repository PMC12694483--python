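"""Apparent nitrogen balance, apparent nitrogen loss rate and classification.

The per-treatment-year ledger is

    N_input   = fertilizer N rate + pre-sowing 0–60 cm soil inorganic N
    N_output  = end-of-season soil inorganic N residue
                + plant N accumulation + seasonal N₂O emission
    N_balance = N_input − N_output
    ANLR (%)  = N_balance / N rate × 100        (undefined at zero rate)

all in kg N·ha⁻¹. Biological N fixation, leaching and NH₃ volatilization
are not part of the ledger, so strongly negative balances in unfertilized
plots partly reflect unmeasured inputs ("apparent" balance). The balance
is classified as deficit / near-equilibrium / surplus against configurable
thresholds (default ±20 kg·ha⁻¹).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .core import Pattern, Treatment, UnitPolicy, DEFAULT_POLICY, ValidationError, round_report
from .io import validate_table

#: Rendered for the undefined zero-rate loss rate in report tables.
ANLR_UNDEFINED = "—"

#: Default (low, high) balance thresholds, kg·ha⁻¹.
DEFAULT_THRESHOLDS = (-20.0, 20.0)


class BalanceCategory(str, enum.Enum):
    DEFICIT = "deficit"
    NEAR_EQUILIBRIUM = "near_equilibrium"
    SURPLUS = "surplus"


@dataclass(frozen=True)
class NitrogenBudget:
    """One treatment-year's completed nitrogen ledger (kg·ha⁻¹; anlr %)."""

    year: int
    treatment: Treatment
    initial_soil_n: float
    soil_residue: float
    plant_accumulation: float
    n2o_emission: float
    n_input: float
    n_output: float
    balance: float

    @property
    def n_rate(self) -> float:
        return self.treatment.n_rate

    @property
    def anlr(self) -> float | None:
        """Apparent nitrogen loss rate, %; None when the N rate is zero."""
        if self.n_rate == 0:
            return None
        return self.balance / self.n_rate * 100.0


def n_balance(year: int, treatment: Treatment, *, initial_soil_n: float,
              soil_residue: float, plant_accumulation: float,
              n2o_emission: float) -> NitrogenBudget:
    """Assemble one treatment-year ledger; exact arithmetic, no rounding."""
    components = {
        "initial_soil_n": initial_soil_n, "soil_residue": soil_residue,
        "plant_accumulation": plant_accumulation, "n2o_emission": n2o_emission,
    }
    for name, v in components.items():
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")
    n_in = treatment.n_rate + initial_soil_n
    n_out = soil_residue + plant_accumulation + n2o_emission
    return NitrogenBudget(
        year=year, treatment=treatment, n_input=n_in, n_output=n_out,
        balance=n_in - n_out, **components,
    )


def anlr(budget: NitrogenBudget) -> float | None:
    """Apparent nitrogen loss rate (%); None (rendered "—") at zero rate."""
    return budget.anlr


def classify_balance(budget: NitrogenBudget,
                     thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> BalanceCategory:
    """Deficit / near-equilibrium / surplus against (low, high) thresholds."""
    low, high = thresholds
    if not low < high:
        raise ValidationError(f"thresholds must satisfy low < high, got {thresholds}")
    if budget.balance < low:
        return BalanceCategory.DEFICIT
    if budget.balance > high:
        return BalanceCategory.SURPLUS
    return BalanceCategory.NEAR_EQUILIBRIUM


def budgets_from_components(components: pd.DataFrame) -> list[NitrogenBudget]:
    """Build ledgers from a validated ``budget`` components table."""
    df = validate_table(components, "budget")
    return [
        n_balance(
            int(r.year), Treatment(Pattern(r.pattern), float(r.n_rate)),
            initial_soil_n=r.initial_soil_n_kg_ha,
            soil_residue=r.soil_residue_kg_ha,
            plant_accumulation=r.plant_accumulation_kg_ha,
            n2o_emission=r.n2o_emission_kg_ha,
        )
        for r in df.itertuples()
    ]


def budget_table(budgets: list[NitrogenBudget],
                 policy: UnitPolicy = DEFAULT_POLICY,
                 thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Render budgets as a report table (rounded; "—" for undefined ANLR).

    One row per (pattern, n_rate, year), sorted; column order mirrors the
    conventional published layout: components, then input/output sums,
    balance, ANLR and the classification.
    """
    rows = []
    for b in sorted(budgets, key=lambda b: (b.treatment.pattern.value,
                                            b.treatment.n_rate, b.year)):
        a = b.anlr
        rows.append({
            "pattern": b.treatment.pattern.value,
            "n_rate": b.treatment.n_rate,
            "year": b.year,
            "initial_soil_n_kg_ha": round_report(b.initial_soil_n, policy),
            "soil_residue_kg_ha": round_report(b.soil_residue, policy),
            "plant_accumulation_kg_ha": round_report(b.plant_accumulation, policy),
            "n2o_emission_kg_ha": round_report(b.n2o_emission, policy),
            "n_input_kg_ha": round_report(b.n_input, policy),
            "n_output_kg_ha": round_report(b.n_output, policy),
            "n_balance_kg_ha": round_report(b.balance, policy),
            "anlr_pct": ANLR_UNDEFINED if a is None else round_report(a, policy),
            "category": classify_balance(b, thresholds).value,
        })
    columns = ["pattern", "n_rate", "year", "initial_soil_n_kg_ha",
               "soil_residue_kg_ha", "plant_accumulation_kg_ha",
               "n2o_emission_kg_ha", "n_input_kg_ha", "n_output_kg_ha",
               "n_balance_kg_ha", "anlr_pct", "category"]
    return pd.DataFrame(rows, columns=columns)


def load_reference_components() -> pd.DataFrame:
    """The package's reference budget-component table: the 12-treatment ×
    2-year component values of a published two-year alfalfa ridge–furrow
    field trial, used as the canonical worked example and regression
    fixture."""
    with resources.files("nbudget.data").joinpath(
            "alfalfa_trial_budget_components.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return validate_table(df, "budget")
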