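"""Deterministic, order-independent data-cleaning rules for the raw tables.

Rules (fixed, declared conventions suitable for an automated real-time
algorithm):

* date conflicts: if any dated event (encounter, dispense) precedes the
  enrollment date, enrollment is moved back to the earliest event date; if
  enrollment falls after the ART start date, enrollment is set to the ART
  start date (pre-ART duration becomes 0).
* anthropometrics: adult plausibility bounds weight in [25, 250] kg and
  height in [1.20, 2.20] m; out-of-bounds values are set missing (the record
  is kept); BMI is computed only when both survive.
* partial birth dates: missing day -> 15th of the month; missing month and
  day -> July 1; missing year -> age stays missing. Age at ART start is
  derived in whole years.

Every alteration or exclusion is counted in a :class:`CleaningReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortTables

WEIGHT_BOUNDS_KG = (25.0, 250.0)
HEIGHT_BOUNDS_M = (1.20, 2.20)


@dataclass
class CleaningReport:
    """Counts of records altered or excluded per rule."""

    counts: dict[str, int] = field(default_factory=dict)
    imputed_birthdate_patients: list[str] = field(default_factory=list)

    def add(self, rule: str, n: int = 1) -> None:
        if n < 0:
            raise ValueError("rule counts must be non-negative")
        self.counts[rule] = self.counts.get(rule, 0) + n

    def count(self, rule: str) -> int:
        return self.counts.get(rule, 0)

    def merge(self, other: "CleaningReport") -> "CleaningReport":
        for rule, n in other.counts.items():
            self.add(rule, n)
        self.imputed_birthdate_patients.extend(other.imputed_birthdate_patients)
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["rule", "n_records"]
        )


def resolve_date_conflicts(
    patients: pd.DataFrame, encounters: pd.DataFrame
) -> tuple[pd.DataFrame, CleaningReport]:
    """Fix implausible date relationships in the registry.

    After cleaning no dated encounter precedes enrollment and
    ``art_start_date >= enrollment_date`` for every patient.
    """
    report = CleaningReport()
    out = patients.copy()

    earliest = encounters.groupby("patient_id")["date"].min()
    mapped = out["patient_id"].map(earliest)
    conflict_visit = mapped.notna() & (mapped < out["enrollment_date"])
    out.loc[conflict_visit, "enrollment_date"] = mapped[conflict_visit]
    report.add("enrollment_moved_to_earliest_visit", int(conflict_visit.sum()))

    conflict_art = out["art_start_date"] < out["enrollment_date"]
    out.loc[conflict_art, "enrollment_date"] = out.loc[conflict_art, "art_start_date"]
    report.add("enrollment_set_to_art_start", int(conflict_art.sum()))
    return out, report


def filter_implausible_anthropometrics(
    patients: pd.DataFrame,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Blank out-of-bounds weight/height; compute BMI where both survive."""
    report = CleaningReport()
    out = patients.copy()

    w = pd.to_numeric(out["weight_kg"], errors="coerce")
    bad_w = w.notna() & ~w.between(*WEIGHT_BOUNDS_KG)
    out["weight_kg"] = w.mask(bad_w)
    report.add("weight_out_of_bounds", int(bad_w.sum()))

    h = pd.to_numeric(out["height_m"], errors="coerce")
    bad_h = h.notna() & ~h.between(*HEIGHT_BOUNDS_M)
    out["height_m"] = h.mask(bad_h)
    report.add("height_out_of_bounds", int(bad_h.sum()))

    out["bmi"] = out["weight_kg"] / out["height_m"] ** 2
    return out, report


def impute_partial_birthdate(
    patients: pd.DataFrame,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Impute missing birth day/month and derive age at ART start in whole years."""
    report = CleaningReport()
    out = patients.copy()

    year = pd.to_numeric(out["birth_year"], errors="coerce")
    month = pd.to_numeric(out["birth_month"], errors="coerce")
    day = pd.to_numeric(out["birth_day"], errors="coerce")

    imputed_md = year.notna() & month.isna()
    imputed_d = year.notna() & month.notna() & day.isna()
    month = month.where(~imputed_md, 7.0)
    day = day.where(~(imputed_md | imputed_d), np.nan)
    day = day.where(~imputed_md, 1.0)
    day = day.where(~imputed_d, 15.0)

    report.add("birth_month_day_imputed", int(imputed_md.sum()))
    report.add("birth_day_imputed", int(imputed_d.sum()))
    report.add("birth_year_missing", int(year.isna().sum()))
    flagged = imputed_md | imputed_d
    report.imputed_birthdate_patients.extend(out.loc[flagged, "patient_id"].tolist())

    birth = pd.to_datetime(
        pd.DataFrame({"year": year, "month": month, "day": day}), errors="coerce"
    )
    out["birth_date"] = birth
    art = pd.to_datetime(out["art_start_date"])
    age = (art - birth).dt.days / 365.25
    out["age_at_art_start"] = np.floor(age)
    return out, report


def clean_tables(tables: CohortTables) -> tuple[CohortTables, CleaningReport]:
    """Apply all cleaning rules; idempotent on already-clean bundles."""
    report = CleaningReport()
    cleaned = tables.copy()
    # events usable for the registration-date rule: encounters plus dispenses
    events = pd.concat(
        [
            cleaned.encounters[["patient_id", "date"]],
            cleaned.dispenses.rename(columns={"dispense_date": "date"})[
                ["patient_id", "date"]
            ],
        ],
        ignore_index=True,
    )
    patients, rep = resolve_date_conflicts(cleaned.patients, events)
    report.merge(rep)
    patients, rep = filter_implausible_anthropometrics(patients)
    report.merge(rep)
    patients, rep = impute_partial_birthdate(patients)
    report.merge(rep)
    cleaned.patients = patients
    return cleaned, report
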