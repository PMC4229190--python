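"""ART-failure ascertainment (WHO immunologic/clinical criteria) and cohorts.

Failure criteria evaluated over a follow-up window (day offsets from ART
start, window inclusive at both ends):

* c1: follow-up CD4 falls to the baseline level or below (<=).
* c2: follow-up CD4 falls below 50% of the post-ART peak, where the peak is
  taken over post-ART results strictly preceding the evaluated result (the
  first follow-up therefore cannot fire c2).
* c3: CD4 below 100 cells/ul; by default any single in-window result
  qualifies, with an optional stricter two-consecutive-results rule.
* c4: new WHO stage IV diagnosis in the window, not attributed to immune
  reconstitution syndrome (IRIS).

The 12-month cohort requires >=182 days of potential follow-up, a baseline
CD4 (within -180..+7 days of ART start; waived in sensitivity mode) and a
follow-up CD4 at 182-365 days; the outcome window is days 183-365. The
survival dataset uses up to seven 183-day periods (days 183-1281 for the
outcome), censoring at study close or at loss to follow-up (180 days with no
clinical encounter), whichever comes first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortTables

BASELINE_WINDOW = (-180, 7)  # days around ART start for the baseline CD4
PERIOD_DAYS = 183
N_PERIODS = 7
LTFU_GAP_DAYS = 180
OUTCOME_12M = (183, 365)
OUTCOME_42M = (183, PERIOD_DAYS * N_PERIODS)

CRITERIA = ("c1_below_baseline", "c2_below_half_peak", "c3_below_100", "c4_stage_iv")


@dataclass
class FailureOutcome:
    failed: bool
    failure_date: pd.Timestamp | None = None
    criteria_fired: set[str] = field(default_factory=set)
    censor_reason: str = "none"
    period_index: int | None = None

    def __post_init__(self):
        if self.failed and not self.criteria_fired:
            raise ValueError("failed outcome must name at least one criterion")


def select_baseline_cd4(
    cd4s: pd.DataFrame, art_start: pd.Timestamp
) -> tuple[float, pd.Timestamp] | None:
    """CD4 closest in time to ART start within -180..+7 days, else None.

    Ties in absolute distance go to the earlier (pre-ART) result.
    """
    if not len(cd4s):
        return None
    off = (cd4s["sample_date"] - pd.Timestamp(art_start)).dt.days
    inw = cd4s[(off >= BASELINE_WINDOW[0]) & (off <= BASELINE_WINDOW[1])].copy()
    if not len(inw):
        return None
    inw["_absoff"] = (inw["sample_date"] - pd.Timestamp(art_start)).dt.days.abs()
    inw = inw.sort_values(["_absoff", "sample_date"], kind="mergesort")
    row = inw.iloc[0]
    return float(row["cd4"]), row["sample_date"]


def detect_failure(
    cd4s: pd.DataFrame,
    diagnoses: pd.DataFrame,
    art_start: pd.Timestamp,
    baseline_cd4: float | None,
    outcome_window: tuple[int, int],
    persistent_requires_two: bool = False,
) -> FailureOutcome:
    """Evaluate WHO failure criteria over ``outcome_window`` (inclusive days).

    ``baseline_cd4`` may be None (sensitivity mode); c1 is then skipped.
    Monotone in window extension: later observations can only add failures.
    """
    lo, hi = outcome_window
    if hi < lo:
        raise ValueError("empty outcome window")
    art = pd.Timestamp(art_start)
    fired: dict[str, pd.Timestamp] = {}

    post = cd4s.assign(_off=(cd4s["sample_date"] - art).dt.days) if len(cd4s) else cd4s
    if len(cd4s):
        post = post[post["_off"] >= 1].sort_values(["sample_date"], kind="mergesort")
        inw = post[(post["_off"] >= lo) & (post["_off"] <= hi)]

        peak = -np.inf
        post_iter = post.itertuples(index=False)
        pending = next(post_iter, None)
        below100_prev = False
        for row in inw.itertuples(index=False):
            # advance the running post-ART peak over results strictly earlier
            while pending is not None and pending.sample_date < row.sample_date:
                peak = max(peak, pending.cd4)
                pending = next(post_iter, None)
            if baseline_cd4 is not None and row.cd4 <= baseline_cd4:
                fired.setdefault("c1_below_baseline", row.sample_date)
            if math.isfinite(peak) and row.cd4 < 0.5 * peak:
                fired.setdefault("c2_below_half_peak", row.sample_date)
            if row.cd4 < 100:
                if not persistent_requires_two:
                    fired.setdefault("c3_below_100", row.sample_date)
                elif below100_prev:
                    fired.setdefault("c3_below_100", row.sample_date)
                below100_prev = True
            else:
                below100_prev = False

    if len(diagnoses):
        doff = (diagnoses["date"] - art).dt.days
        qual = diagnoses[
            (doff >= lo)
            & (doff <= hi)
            & diagnoses["who_stage_iv"].astype(bool)
            & ~diagnoses["iris_flag"].astype(bool)
        ]
        if len(qual):
            fired["c4_stage_iv"] = qual["date"].min()

    if not fired:
        return FailureOutcome(failed=False)
    failure_date = min(fired.values())
    at_first = {c for c, d in fired.items() if d == failure_date}
    return FailureOutcome(failed=True, failure_date=failure_date, criteria_fired=at_first)


def build_baseline_profiles(
    tables: CohortTables, summaries: pd.DataFrame
) -> pd.DataFrame:
    """Per-patient baseline covariates joined with adherence summaries."""
    pats = tables.patients
    cd4_by = dict(tuple(tables.cd4.groupby("patient_id"))) if len(tables.cd4) else {}
    empty = tables.cd4.iloc[0:0]
    base_vals, base_dates = [], []
    for pid, art in zip(pats["patient_id"], pats["art_start_date"]):
        sel = select_baseline_cd4(cd4_by.get(pid, empty), art)
        base_vals.append(sel[0] if sel else np.nan)
        base_dates.append(sel[1] if sel else pd.NaT)
    prof = pats[
        ["patient_id", "sex", "site", "marital_status", "residence_zone", "regimen"]
    ].copy()
    prof["male"] = pats["sex"].eq("male")
    prof["baseline_cd4"] = base_vals
    prof["baseline_cd4_date"] = base_dates
    prof["baseline_bmi"] = pats["bmi"] if "bmi" in pats.columns else np.nan
    prof["age_at_art_start"] = (
        pats["age_at_art_start"] if "age_at_art_start" in pats.columns else np.nan
    )
    prof["pre_art_days"] = (
        (pats["art_start_date"] - pats["enrollment_date"]).dt.days.clip(lower=0)
    )
    prof["art_start_year"] = pats["art_start_date"].dt.year
    prof["art_start_date"] = pats["art_start_date"]
    return prof.merge(summaries, on="patient_id", how="left")


def _followup_days(art_start, study_close) -> int:
    return (pd.Timestamp(study_close) - pd.Timestamp(art_start)).days


def build_cohort_12m(
    tables: CohortTables,
    summaries: pd.DataFrame,
    study_close: pd.Timestamp,
    sensitivity: bool = False,
    persistent_requires_two: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """12-month analysis rows plus an exclusion flow (counts conserve)."""
    prof = build_baseline_profiles(tables, summaries)
    cd4_by = dict(tuple(tables.cd4.groupby("patient_id"))) if len(tables.cd4) else {}
    diag_by = (
        dict(tuple(tables.diagnoses.groupby("patient_id")))
        if len(tables.diagnoses)
        else {}
    )
    empty_cd4 = tables.cd4.iloc[0:0]
    empty_diag = tables.diagnoses.iloc[0:0]

    flow = {
        "total": len(prof),
        "excluded_insufficient_followup": 0,
        "excluded_no_baseline_cd4": 0,
        "excluded_no_followup_cd4": 0,
        "included": 0,
    }
    rows = []
    for row in prof.itertuples(index=False):
        if _followup_days(row.art_start_date, study_close) < 182:
            flow["excluded_insufficient_followup"] += 1
            continue
        has_baseline = not pd.isna(row.baseline_cd4)
        if not has_baseline and not sensitivity:
            flow["excluded_no_baseline_cd4"] += 1
            continue
        cd4s = cd4_by.get(row.patient_id, empty_cd4)
        off = (
            (cd4s["sample_date"] - row.art_start_date).dt.days
            if len(cd4s)
            else pd.Series(dtype=int)
        )
        if not ((off >= 182) & (off <= 365)).any():
            flow["excluded_no_followup_cd4"] += 1
            continue
        flow["included"] += 1
        outcome = detect_failure(
            cd4s,
            diag_by.get(row.patient_id, empty_diag),
            row.art_start_date,
            float(row.baseline_cd4) if has_baseline else None,
            OUTCOME_12M,
            persistent_requires_two=persistent_requires_two,
        )
        rec = row._asdict()
        rec["failed"] = outcome.failed
        rec["failure_date"] = outcome.failure_date
        rec["criteria_fired"] = ";".join(sorted(outcome.criteria_fired))
        rows.append(rec)
    cohort = pd.DataFrame(rows)
    assert flow["included"] + sum(
        v for k, v in flow.items() if k.startswith("excluded_")
    ) == flow["total"]
    return cohort, flow


def build_survival_dataset(
    tables: CohortTables,
    summaries: pd.DataFrame,
    study_close: pd.Timestamp,
    sensitivity: bool = False,
    persistent_requires_two: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-patient discrete time-to-event rows over seven 183-day periods."""
    prof = build_baseline_profiles(tables, summaries)
    cd4_by = dict(tuple(tables.cd4.groupby("patient_id"))) if len(tables.cd4) else {}
    diag_by = (
        dict(tuple(tables.diagnoses.groupby("patient_id")))
        if len(tables.diagnoses)
        else {}
    )
    last_enc = (
        tables.encounters.groupby("patient_id")["date"].max()
        if len(tables.encounters)
        else pd.Series(dtype="datetime64[ns]")
    )
    empty_cd4 = tables.cd4.iloc[0:0]
    empty_diag = tables.diagnoses.iloc[0:0]

    flow = {
        "total": len(prof),
        "excluded_insufficient_followup": 0,
        "excluded_no_baseline_cd4": 0,
        "excluded_no_followup_cd4": 0,
        "included": 0,
    }
    rows = []
    for row in prof.itertuples(index=False):
        followup = _followup_days(row.art_start_date, study_close)
        if followup < 365:
            flow["excluded_insufficient_followup"] += 1
            continue
        has_baseline = not pd.isna(row.baseline_cd4)
        if not has_baseline and not sensitivity:
            flow["excluded_no_baseline_cd4"] += 1
            continue
        cd4s = cd4_by.get(row.patient_id, empty_cd4)
        off = (
            (cd4s["sample_date"] - row.art_start_date).dt.days
            if len(cd4s)
            else pd.Series(dtype=int)
        )
        if not ((off >= 182) & (off <= OUTCOME_42M[1])).any():
            flow["excluded_no_followup_cd4"] += 1
            continue
        flow["included"] += 1

        censor_period = min(N_PERIODS, followup // PERIOD_DAYS)
        censor_reason = "study_close"
        le = last_enc.get(row.patient_id, pd.NaT)
        if not pd.isna(le):
            ltfu_day = (le - row.art_start_date).days + LTFU_GAP_DAYS
            if ltfu_day < followup:
                ltfu_period = max(1, math.ceil(ltfu_day / PERIOD_DAYS))
                if ltfu_period <= censor_period:
                    censor_period = ltfu_period
                    censor_reason = "ltfu"
        censor_period = max(1, censor_period)

        outcome = detect_failure(
            cd4s,
            diag_by.get(row.patient_id, empty_diag),
            row.art_start_date,
            float(row.baseline_cd4) if has_baseline else None,
            OUTCOME_42M,
            persistent_requires_two=persistent_requires_two,
        )
        event = False
        period = censor_period
        if outcome.failed:
            fail_period = math.ceil(
                (outcome.failure_date - row.art_start_date).days / PERIOD_DAYS
            )
            if fail_period <= censor_period:
                event = True
                period = max(1, fail_period)
                censor_reason = "none"
        rec = row._asdict()
        rec["event"] = event
        rec["period"] = period
        rec["censor_reason"] = censor_reason
        rec["failure_date"] = outcome.failure_date if event else pd.NaT
        rows.append(rec)
    surv = pd.DataFrame(rows)
    assert flow["included"] + sum(
        v for k, v in flow.items() if k.startswith("excluded_")
    ) == flow["total"]
    return surv, flow
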