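"""Pharmacy-refill and self-reported adherence measures over a fixed window.

Five measures are computed per patient over the first six months (182 days,
day offsets 0..181 counted from the ART start date inclusive):

* MPR (medication possession ratio): total days of supply dispensed inside
  the window divided by the window length, truncated at 1. Supply is credited
  in full even when it extends past the window end.
* PDC (proportion of days covered): fraction of window days covered by the
  most recently dispensed supply; a new pickup supersedes leftover stock, so
  PDC <= MPR always.
* TVR (timely visit ratio): fraction of refill due dates (dispense date +
  days supplied) falling inside the window that are met by a pickup no more
  than 2 days late; early pickups count as timely.
* VAS mean: average visual-analogue-scale self-report, rescaled to [0, 1].
* %NoMD: proportion of assessments reporting no missed doses in the last
  3 days.

Multi-drug regimens: the days supplied for a dispense is the minimum across
its drugs; if any drug's quantity is missing the whole dispense quantity is
missing (a minimum over a set with an unknown member is unknown). The
interval from a missing-quantity dispense to the next dispense (or window
end) is excluded from both the numerator and the denominator of MPR and PDC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

WINDOW_DAYS = 182
TVR_GRACE_DAYS = 2


@dataclass(frozen=True)
class RegimenDispense:
    """One pharmacy dispense collapsed to the regimen level."""

    date: pd.Timestamp
    days_supplied: float | None  # None when any per-drug quantity is missing

    def __post_init__(self):
        if self.days_supplied is not None and not self.days_supplied > 0:
            raise ValueError("days_supplied must be > 0 when present")


@dataclass(frozen=True)
class Window:
    """A fixed observation window of ``n_days`` days starting on ``start``."""

    start: pd.Timestamp
    n_days: int = WINDOW_DAYS

    def offset(self, date: pd.Timestamp) -> int:
        return (pd.Timestamp(date) - pd.Timestamp(self.start)).days

    def contains_offset(self, off: int) -> bool:
        return 0 <= off < self.n_days


@dataclass
class AdherenceSummary:
    """Per-patient five-measure summary with availability encoded as NaN."""

    patient_id: str
    window: Window
    mpr: float
    pdc: float
    tvr: float
    vas_mean: float
    pct_no_md: float
    n_assessments: int
    any_clinician_assessment: bool


def regimen_days_supplied(
    dispense_date: pd.Timestamp, per_drug_days: dict[str, float | None]
) -> RegimenDispense:
    """Collapse per-drug days supplied to the regimen minimum.

    Missing propagates: if any drug's quantity is unknown, the regimen
    quantity is unknown.
    """
    if not per_drug_days:
        raise ValueError("dispense lists no drugs")
    vals = list(per_drug_days.values())
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        return RegimenDispense(pd.Timestamp(dispense_date), None)
    return RegimenDispense(pd.Timestamp(dispense_date), float(min(vals)))


def _window_layout(
    dispenses: Sequence[RegimenDispense], window: Window
) -> tuple[list[tuple[int, float | None]], list[tuple[int, int]], int]:
    """Sorted in-window (offset, days) pairs, excluded intervals, effective denom."""
    inw = sorted(
        (window.offset(d.date), d.days_supplied)
        for d in dispenses
        if window.contains_offset(window.offset(d.date))
    )
    excluded: list[tuple[int, int]] = []
    for i, (off, days) in enumerate(inw):
        if days is None:
            end = inw[i + 1][0] if i + 1 < len(inw) else window.n_days
            excluded.append((off, end))
    denom = window.n_days - sum(e - s for s, e in excluded)
    return inw, excluded, denom


def compute_mpr(dispenses: Sequence[RegimenDispense], window: Window) -> float:
    """Medication possession ratio, truncated at 1; NaN when undefined."""
    if window.n_days <= 0:
        raise ValueError("window length must be positive")
    inw, _, denom = _window_layout(dispenses, window)
    if not inw or denom <= 0:
        return float("nan")
    total = sum(days for _, days in inw if days is not None)
    return min(1.0, total / denom)


def compute_pdc(dispenses: Sequence[RegimenDispense], window: Window) -> float:
    """Proportion of days covered under supersession; NaN when undefined."""
    if window.n_days <= 0:
        raise ValueError("window length must be positive")
    inw, _, denom = _window_layout(dispenses, window)
    if not inw or denom <= 0:
        return float("nan")
    covered = 0
    for i, (off, days) in enumerate(inw):
        if days is None:
            continue
        end = min(off + days, window.n_days)
        if i + 1 < len(inw):
            end = min(end, inw[i + 1][0])  # superseded by the next pickup
        covered += max(0, int(end) - off)
    return covered / denom


def compute_tvr(dispenses: Sequence[RegimenDispense], window: Window) -> float:
    """Timely visit ratio over refill due dates inside the window.

    A due date later than the window end is not judged (censoring-safe).
    """
    if window.n_days <= 0:
        raise ValueError("window length must be positive")
    dates = sorted(window.offset(d.date) for d in dispenses)
    opportunities = 0
    timely = 0
    for d in dispenses:
        if d.days_supplied is None:
            continue
        off = window.offset(d.date)
        due = off + int(d.days_supplied)
        if not window.contains_offset(due):
            continue
        opportunities += 1
        if any(off < x <= due + TVR_GRACE_DAYS for x in dates):
            timely += 1
    if opportunities == 0:
        return float("nan")
    return timely / opportunities


def summarize_self_report(
    assessments: pd.DataFrame, window: Window
) -> tuple[float, float, int, bool]:
    """(vas_mean on [0,1], pct_no_md, n_assessments, any_clinician) in window."""
    if len(assessments):
        bad = ~assessments["vas_pct"].between(0, 100) & assessments["vas_pct"].notna()
        if bad.any():
            raise ValueError(
                f"VAS outside [0, 100] in rows {assessments.index[bad].tolist()}"
            )
        offs = assessments["date"].map(window.offset)
        inw = assessments[(offs >= 0) & (offs < window.n_days)]
    else:
        inw = assessments
    n = len(inw)
    if n == 0:
        return float("nan"), float("nan"), 0, False
    vas = inw["vas_pct"].mean() / 100.0
    pct = float(inw["no_missed_doses_3d"].mean())
    any_clin = bool((inw["assessor"] == "clinician").any())
    return float(vas), pct, n, any_clin


def regimen_dispenses_from_events(dispense_events: pd.DataFrame) -> list[RegimenDispense]:
    """Collapse a long per-drug dispense table (one patient) to regimen dispenses."""
    out = []
    for date, grp in dispense_events.groupby("dispense_date"):
        per_drug = dict(zip(grp["drug"], grp["days_supplied"]))
        per_drug = {
            k: (None if pd.isna(v) else float(v)) for k, v in per_drug.items()
        }
        out.append(regimen_days_supplied(date, per_drug))
    return out


def baseline_adherence(
    patient_id: str,
    art_start: pd.Timestamp,
    dispense_events: pd.DataFrame,
    assessments: pd.DataFrame,
) -> AdherenceSummary:
    """All five first-6-months measures for one patient."""
    window = Window(pd.Timestamp(art_start), WINDOW_DAYS)
    disp = regimen_dispenses_from_events(dispense_events)
    vas_mean, pct_no_md, n_assess, any_clin = summarize_self_report(assessments, window)
    return AdherenceSummary(
        patient_id=patient_id,
        window=window,
        mpr=compute_mpr(disp, window),
        pdc=compute_pdc(disp, window),
        tvr=compute_tvr(disp, window),
        vas_mean=vas_mean,
        pct_no_md=pct_no_md,
        n_assessments=n_assess,
        any_clinician_assessment=any_clin,
    )


def summarize_cohort(
    patients: pd.DataFrame, dispenses: pd.DataFrame, assessments: pd.DataFrame
) -> pd.DataFrame:
    """One adherence-summary row per patient in the registry."""
    known = set(patients["patient_id"])
    disp_by = dict(tuple(dispenses.groupby("patient_id"))) if len(dispenses) else {}
    assess_by = dict(tuple(assessments.groupby("patient_id"))) if len(assessments) else {}
    empty_disp = dispenses.iloc[0:0]
    empty_assess = assessments.iloc[0:0]
    rows = []
    for pid, art in zip(patients["patient_id"], patients["art_start_date"]):
        if pid not in known:  # pragma: no cover - registry is the id source
            raise KeyError(pid)
        s = baseline_adherence(
            pid, art, disp_by.get(pid, empty_disp), assess_by.get(pid, empty_assess)
        )
        rows.append(
            (pid, s.mpr, s.pdc, s.tvr, s.vas_mean, s.pct_no_md,
             s.n_assessments, s.any_clinician_assessment)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "mpr", "pdc", "tvr", "vas_mean", "pct_no_md",
            "n_assessments", "any_clinician_assessment",
        ],
    )
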