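"""Reading and writing the six EMR-style tables as delimited text.

Tables are UTF-8 CSV with a header row and ISO-8601 dates. Missing values
are empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

#: table name -> (date columns, required columns)
TABLE_SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "patients": (
        ("enrollment_date", "art_start_date"),
        (
            "patient_id", "sex", "birth_year", "birth_month", "birth_day",
            "marital_status", "residence_zone", "site", "enrollment_date",
            "art_start_date", "regimen", "weight_kg", "height_m",
        ),
    ),
    "dispenses": (
        ("dispense_date",),
        ("patient_id", "dispense_date", "drug", "days_supplied"),
    ),
    "cd4": (("sample_date",), ("patient_id", "sample_date", "cd4")),
    "assessments": (
        ("date",),
        ("patient_id", "date", "vas_pct", "no_missed_doses_3d", "assessor"),
    ),
    "encounters": (("date",), ("patient_id", "date")),
    "diagnoses": (
        ("date",),
        ("patient_id", "date", "who_stage_iv", "iris_flag"),
    ),
}


@dataclass
class CohortTables:
    """Bundle of the six EMR-style tables, one DataFrame each."""

    patients: pd.DataFrame
    dispenses: pd.DataFrame
    cd4: pd.DataFrame
    assessments: pd.DataFrame
    encounters: pd.DataFrame
    diagnoses: pd.DataFrame

    def copy(self) -> "CohortTables":
        return CohortTables(**{f.name: getattr(self, f.name).copy() for f in fields(self)})

    def items(self):
        for f in fields(self):
            yield f.name, getattr(self, f.name)


def write_tables(tables: CohortTables, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        out = df.copy()
        for col in TABLE_SCHEMAS[name][0]:
            if col in out.columns:
                out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        out.to_csv(outdir / f"{name}.csv", index=False)


def read_tables(indir: str | Path) -> CohortTables:
    indir = Path(indir)
    loaded = {}
    for name, (date_cols, _) in TABLE_SCHEMAS.items():
        path = indir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing table file: {path}")
        df = pd.read_csv(path)
        for col in date_cols:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        loaded[name] = df
    return CohortTables(**loaded)
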