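"""CSV schemas and validated table I/O.

All tables are comma-separated UTF-8 with a header row. Each schema names
its required columns, their dtypes, and row-level invariants; violations
raise :class:`~nbudget.core.SchemaError` (structure) or
:class:`~nbudget.core.ValidationError` (values), always naming the column
and 1-based data row involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import SchemaError, ValidationError

_PATTERNS = ("FP", "JM", "PM")
_POSITIONS = ("flat", "ridge", "furrow")


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: Mapping[str, str]  # column -> dtype kind: "num", "int", "str", "date"
    checks: Sequence[tuple[str, Callable[[pd.Series], pd.Series], str]] = ()

    def required(self) -> list[str]:
        return list(self.columns)


def _nonneg(s: pd.Series) -> pd.Series:
    return s >= 0


def _positive(s: pd.Series) -> pd.Series:
    return s > 0


def _pct(s: pd.Series) -> pd.Series:
    return (s >= 0) & (s <= 100)


SCHEMAS: dict[str, TableSchema] = {}


def _register(schema: TableSchema) -> None:
    SCHEMAS[schema.name] = schema


_register(TableSchema(
    "soil",
    {
        "year": "int", "pattern": "str", "n_rate": "num", "replicate": "int",
        "date": "date", "depth_top_cm": "num", "depth_bottom_cm": "num",
        "bulk_density_g_cm3": "num", "no3_mg_kg": "num", "nh4_mg_kg": "num",
    },
    checks=[
        ("n_rate", _nonneg, "nitrogen rate must be >= 0"),
        ("bulk_density_g_cm3", _positive, "bulk density must be > 0"),
        ("no3_mg_kg", _nonneg, "NO3-N concentration must be >= 0"),
        ("nh4_mg_kg", _nonneg, "NH4-N concentration must be >= 0"),
        ("replicate", _positive, "replicate must be >= 1"),
    ],
))

_register(TableSchema(
    "plant",
    {
        "year": "int", "pattern": "str", "n_rate": "num", "replicate": "int",
        "cut": "int", "date": "date", "leaf_n_pct": "num", "stem_n_pct": "num",
        "leaf_dm_kg_ha": "num", "stem_dm_kg_ha": "num",
    },
    checks=[
        ("n_rate", _nonneg, "nitrogen rate must be >= 0"),
        ("leaf_n_pct", _pct, "leaf N content must be a percent in [0, 100]"),
        ("stem_n_pct", _pct, "stem N content must be a percent in [0, 100]"),
        ("leaf_dm_kg_ha", _nonneg, "leaf dry matter must be >= 0"),
        ("stem_dm_kg_ha", _nonneg, "stem dry matter must be >= 0"),
        ("cut", _positive, "cut index must be >= 1"),
    ],
))

_register(TableSchema(
    "chamber",
    {
        "year": "int", "pattern": "str", "n_rate": "num", "replicate": "int",
        "date": "date", "position": "str", "height_m": "num", "temp_c": "num",
        "minute": "num", "conc_ul_l": "num",
    },
    checks=[
        ("height_m", _positive, "chamber height must be > 0"),
        ("temp_c", lambda s: s > -273, "temperature must exceed -273 degC"),
        ("minute", _nonneg, "sampling minute must be >= 0"),
    ],
))

_register(TableSchema(
    "flux",
    {
        "year": "int", "pattern": "str", "n_rate": "num", "replicate": "int",
        "date": "date", "flux_ug_m2_h": "num", "r_squared": "num", "n_points": "int",
    },
    checks=[("n_points", lambda s: s >= 2, "slope fit needs >= 2 points")],
))

# Per-treatment-year budget components: the ledger inputs (Table-2 layout).
_register(TableSchema(
    "budget",
    {
        "year": "int", "pattern": "str", "n_rate": "num",
        "initial_soil_n_kg_ha": "num", "soil_residue_kg_ha": "num",
        "plant_accumulation_kg_ha": "num", "n2o_emission_kg_ha": "num",
    },
    checks=[
        ("n_rate", _nonneg, "nitrogen rate must be >= 0"),
        ("initial_soil_n_kg_ha", _nonneg, "initial soil N must be >= 0"),
        ("soil_residue_kg_ha", _nonneg, "soil residue must be >= 0"),
        ("plant_accumulation_kg_ha", _nonneg, "plant accumulation must be >= 0"),
        ("n2o_emission_kg_ha", _nonneg, "N2O emission must be >= 0"),
    ],
))


def _coerce(df: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    out = df.copy()
    for col, kind in schema.columns.items():
        raw = out[col]
        try:
            if kind == "num":
                out[col] = pd.to_numeric(raw)
            elif kind == "int":
                out[col] = pd.to_numeric(raw).astype("int64")
            elif kind == "date":
                out[col] = pd.to_datetime(raw, format="ISO8601").dt.date
            else:
                out[col] = raw.astype(str)
        except (ValueError, TypeError) as exc:
            bad = _first_bad(raw, kind)
            raise SchemaError(
                f"{schema.name}: column '{col}' is not parseable as {kind}"
                + (f" (first bad value {bad[1]!r} at data row {bad[0]})" if bad else "")
            ) from exc
    if kind_has_numeric(schema):
        num_cols = [c for c, k in schema.columns.items() if k in ("num", "int")]
        bad = out[num_cols].isna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise SchemaError(
                f"{schema.name}: missing/non-numeric value in column "
                f"'{num_cols[c]}' at data row {r + 1}"
            )
    return out


def kind_has_numeric(schema: TableSchema) -> bool:
    return any(k in ("num", "int") for k in schema.columns.values())


def _first_bad(raw: pd.Series, kind: str):
    for i, v in enumerate(raw, start=1):
        try:
            if kind in ("num", "int"):
                float(v)
            elif kind == "date":
                pd.Timestamp(v)
        except (ValueError, TypeError):
            return i, v
    return None


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Validate (and dtype-coerce) a DataFrame against a named schema."""
    try:
        sch = SCHEMAS[schema]
    except KeyError:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    missing = [c for c in sch.required() if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema}: missing column(s) {missing}")
    out = _coerce(df, sch)
    if "pattern" in out.columns:
        bad = ~out["pattern"].isin(_PATTERNS)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValidationError(
                f"{schema}: unknown pattern {out['pattern'][bad].iloc[0]!r} "
                f"at data row {row}; expected one of {_PATTERNS}"
            )
    if "position" in out.columns:
        bad = ~out["position"].isin(_POSITIONS)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValidationError(
                f"{schema}: unknown position at data row {row}; "
                f"expected one of {_POSITIONS}"
            )
    for col, check, msg in sch.checks:
        ok = check(out[col])
        if not ok.all():
            row = int(np.flatnonzero(~ok.to_numpy())[0]) + 1
            raise ValidationError(
                f"{schema}: {msg} (column '{col}', data row {row}, "
                f"value {out[col].iloc[row - 1]!r})"
            )
    return out.reset_index(drop=True)


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV and validate it against a named schema."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    """Write a CSV; if ``schema`` is given the frame is validated first."""
    if schema is not None:
        df = validate_table(df, schema)
    df.to_csv(path, index=False)
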