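from __future__ import annotations

import pandas as pd
import pytest

from artrisk.adherence import summarize_cohort
from artrisk.cleaning import clean_tables
from artrisk.config import SimConfig
from artrisk.synthetic_emr import generate_cohort, ground_truth


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_patients=1200, seed=20260901)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Generated tables, cleaned tables, adherence summaries, and truth."""
    tables = generate_cohort(small_config)
    cleaned, _ = clean_tables(tables)
    summaries = summarize_cohort(
        cleaned.patients, cleaned.dispenses, cleaned.assessments
    )
    truth = ground_truth(small_config, tables)
    return {
        "config": small_config,
        "tables": tables,
        "cleaned": cleaned,
        "summaries": summaries,
        "truth": truth,
    }


def make_patients(rows: list[dict]) -> pd.DataFrame:
    """Registry frame from sparse dicts with sensible defaults."""
    defaults = {
        "patient_id": None,
        "sex": "female",
        "birth_year": 1970,
        "birth_month": 6,
        "birth_day": 10,
        "marital_status": "single",
        "residence_zone": "same",
        "site": "HSA",
        "enrollment_date": "2006-01-01",
        "art_start_date": "2006-03-01",
        "regimen": "AZT-3TC-EFV",
        "weight_kg": 60.0,
        "height_m": 1.65,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["patient_id"] = f"T{i + 1:03d}"
        rec.update(row)
        out.append(rec)
    df = pd.DataFrame(out)
    for col in ("enrollment_date", "art_start_date"):
        df[col] = pd.to_datetime(df[col])
    return df
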