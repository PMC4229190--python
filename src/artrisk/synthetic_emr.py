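"""Synthetic EMR cohort generator with known ground truth.

Emulates the structure of a longitudinal HIV clinic extract: a patient
registry, pharmacy dispense events (per-drug days supplied), CD4 laboratory
results, self-reported adherence assessments, clinical encounters, and WHO
stage-IV diagnosis events.

The generative model: each patient carries a latent adherence propensity on
[0, 1] that drives refill delays (poor adherers pick up late) and the odds
of ever providing a self-reported assessment (poor adherers less often do).
Twelve-month treatment failure follows a logistic model on four binary risk
factors - low latent adherence, high baseline CD4, short pre-ART enrollment,
male sex - with the intercept calibrated so the population prevalence matches
the configured target. CD4 trajectories are drawn conditional on failure
status: recovery for non-failures, decline toward/below baseline around the
latent failure time for failures, so the WHO-criteria detector has signal.

A small amount of data-quality mess (date conflicts, implausible
anthropometrics, partial birth dates, missing dispense quantities) is
injected at fixed rates so the cleaning rules have real work to do.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy import optimize, special, stats

from .config import SimConfig
from .io import CohortTables

# Event-level mess rates (data-quality artifacts, independent of propensity)
_RATE_ENROLL_AFTER_ART = 0.01
_RATE_VISIT_BEFORE_ENROLL = 0.005
_RATE_WEIGHT_X10 = 0.005
_RATE_HEIGHT_CM = 0.005
_RATE_BIRTH_DAY_MISSING = 0.10
_RATE_BIRTH_MONTH_DAY_MISSING = 0.05
_RATE_ANTHRO_MISSING = 0.25

_REGIMENS = {
    "AZT-3TC-EFV": ("AZT", "3TC", "EFV"),
    "AZT-3TC-NVP": ("AZT", "3TC", "NVP"),
    "TDF-3TC-EFV": ("TDF", "3TC", "EFV"),
    "D4T-3TC-NVP": ("D4T", "3TC", "NVP"),
}
_REGIMEN_P = (0.49, 0.29, 0.20, 0.02)

#: Binary risk-factor thresholds on the latent scale
LOW_PDC_CUT = 0.80
HIGH_CD4_CUT = 250.0
SHORT_PRE_ART_CUT = 160.0


def _gamma_shape_for_iqr(mean: float, iqr_width: float) -> float:
    """Shape k of a gamma with the given mean whose IQR has the given width."""
    target = iqr_width / mean

    def f(k: float) -> float:
        return (stats.gamma.ppf(0.75, k) - stats.gamma.ppf(0.25, k)) / k - target

    return optimize.brentq(f, 0.2, 400.0)


def _calibrate_intercept(linear: np.ndarray, target: float) -> float:
    """Intercept a such that mean(expit(a + linear)) == target."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf

    def f(a: float) -> float:
        return float(np.mean(special.expit(a + linear))) - target

    return optimize.brentq(f, -30.0, 30.0)


def sample_patient_frame(config: SimConfig, rng: Generator | None = None) -> pd.DataFrame:
    """Draw the per-patient latent frame: covariates, propensity, failure truth.

    Deterministic given ``config`` (uses the first child stream of
    ``config.seed`` when ``rng`` is not supplied), which is what lets
    :func:`ground_truth` re-derive the latent state from the config alone.
    """
    config.validate()
    if rng is None:
        rng = default_rng(SeedSequence(config.seed).spawn(2)[0])
    n = config.n_patients

    propensity = np.clip(
        rng.normal(config.adherence_propensity_mean, config.adherence_propensity_sd, n),
        0.02,
        1.0,
    )
    male = rng.random(n) < 0.425
    site = np.where(rng.random(n) < 0.5, "HSA", "HSM")
    marital = rng.choice(
        ["single", "married", "widowed", "unknown"], n, p=[0.25, 0.58, 0.14, 0.03]
    )
    residence = rng.choice(
        ["same", "adjacent", "non_adjacent", "missing"], n, p=[0.34, 0.16, 0.48, 0.02]
    )
    regimen = rng.choice(list(_REGIMENS), n, p=_REGIMEN_P)
    age_at_art = np.clip(rng.normal(38.4, 11.4, n), 16.0, 80.0)
    cd4_true = rng.gamma(1.3, 208.0 / 1.3, n)
    pre_art_days = np.rint(rng.exponential(292.0, n)).astype(int)

    # day offsets from study_start; leave room so most patients are observable
    art_start_day = rng.integers(0, config.study_span_days - 120, n)
    enrollment_day = art_start_day - pre_art_days

    low_pdc = propensity < LOW_PDC_CUT
    high_cd4 = cd4_true >= HIGH_CD4_CUT
    short_pre_art = pre_art_days <= SHORT_PRE_ART_CUT

    eff = config.effect_log_odds
    linear = (
        eff.get("low_pdc", 0.0) * low_pdc
        + eff.get("high_cd4", 0.0) * high_cd4
        + eff.get("short_pre_art", 0.0) * short_pre_art
        + eff.get("male", 0.0) * male
    ).astype(float)
    intercept = _calibrate_intercept(linear, config.failure_prevalence_12m)
    p_fail = special.expit(intercept + linear)
    fail_12m = rng.random(n) < p_fail

    # failure day: within months ~7-12 for 12-month failures; later failures
    # occur among the rest with probability increasing in p_fail, giving the
    # long-horizon survival curves their separation by risk.
    fail_day = np.full(n, np.inf)
    fail_day[fail_12m] = rng.integers(200, 361, int(fail_12m.sum()))
    late = (~fail_12m) & (rng.random(n) < np.clip(0.6 * p_fail, 0.0, 0.95))
    fail_day[late] = rng.integers(366, 1261, int(late.sum()))

    # self-report missingness: logistic in (1 - propensity), intercept
    # calibrated to the configured marginal rate, so poor adherers are the
    # ones who tend to lack self-reported measures.
    r = config.missing_self_report_rate
    if r <= 0.0:
        p_miss_sr = np.zeros(n)
    elif r >= 1.0:
        p_miss_sr = np.ones(n)
    else:
        sr_linear = 4.0 * (1.0 - propensity)
        p_miss_sr = special.expit(_calibrate_intercept(sr_linear, r) + sr_linear)
    no_self_report = rng.random(n) < p_miss_sr

    miss_base_cd4 = rng.random(n) < config.missing_baseline_cd4_rate
    miss_follow_cd4 = rng.random(n) < config.missing_followup_cd4_rate

    # dropout from care (drives loss to follow-up), more likely for poor adherers
    p_drop = np.clip(0.05 + 0.45 * (1.0 - propensity), 0.0, 0.7)
    dropout_rel = np.where(
        rng.random(n) < p_drop, rng.integers(120, 1400, n), np.iinfo(np.int32).max
    )

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:06d}" for i in range(n)],
            "male": male,
            "site": site,
            "marital_status": marital,
            "residence_zone": residence,
            "regimen": regimen,
            "age_at_art": age_at_art,
            "propensity": propensity,
            "cd4_true": cd4_true,
            "pre_art_days": pre_art_days,
            "enrollment_day": enrollment_day,
            "art_start_day": art_start_day,
            "low_pdc": low_pdc,
            "high_cd4": high_cd4,
            "short_pre_art": short_pre_art,
            "p_fail": p_fail,
            "true_failure_12m": fail_12m,
            "fail_day": fail_day,
            "no_self_report": no_self_report,
            "miss_baseline_cd4": miss_base_cd4,
            "miss_followup_cd4": miss_follow_cd4,
            "dropout_rel_day": dropout_rel,
        }
    )


def _cd4_at(t: float, cd4_true: float, fail_day: float, rng: Generator) -> float:
    """CD4 value at day t post-ART: recovery, or decline around failure."""
    decline_start = fail_day - 120.0
    if math.isfinite(fail_day) and t >= decline_start:
        frac = min(1.0, (t - decline_start) / 240.0)
        mean = cd4_true * (1.05 - 0.6 * frac)
    else:
        mean = cd4_true + 180.0 * (1.0 - math.exp(-t / 240.0))
    return max(1.0, mean + rng.normal(0.0, 30.0))


def generate_cohort(config: SimConfig) -> CohortTables:
    """Generate the six EMR-style tables for a synthetic cohort.

    Deterministic given ``config`` (including its seed). Every patient has at
    least one dispense unless care ends before their first pickup window.
    """
    config.validate()
    frame = sample_patient_frame(config)
    rng = default_rng(SeedSequence(config.seed).spawn(2)[1])
    span = config.study_span_days

    shape = _gamma_shape_for_iqr(
        config.dispense_days_mean,
        config.dispense_days_iqr[1] - config.dispense_days_iqr[0],
    )
    scale = config.dispense_days_mean / shape

    pat_rows, disp_rows, cd4_rows, assess_rows, enc_rows, diag_rows = (
        [], [], [], [], [], [],
    )

    for row in frame.itertuples(index=False):
        pid = row.patient_id
        art = int(row.art_start_day)
        enroll = int(row.enrollment_day)
        prop = float(row.propensity)
        active_end = int(min(span - art, row.dropout_rel_day))  # days post-ART

        # --- registry, with injected mess -------------------------------
        if rng.random() < _RATE_ENROLL_AFTER_ART:
            enroll = art + int(rng.integers(5, 40))
        birth_year_offset = row.age_at_art  # age in years at ART start
        art_date = pd.Timestamp(config.study_start) + pd.Timedelta(days=art)
        birth = art_date - pd.Timedelta(days=round(birth_year_offset * 365.25))
        by, bm, bd = birth.year, birth.month, birth.day
        u = rng.random()
        if u < _RATE_BIRTH_MONTH_DAY_MISSING:
            bm = bd = None
        elif u < _RATE_BIRTH_MONTH_DAY_MISSING + _RATE_BIRTH_DAY_MISSING:
            bd = None
        weight = float(np.clip(rng.normal(58.0, 10.0), 35.0, 120.0))
        height = float(np.clip(rng.normal(1.63, 0.08), 1.40, 1.95))
        if rng.random() < _RATE_ANTHRO_MISSING:
            weight = np.nan
        elif rng.random() < _RATE_WEIGHT_X10:
            weight *= 10.0
        if rng.random() < _RATE_ANTHRO_MISSING:
            height = np.nan
        elif rng.random() < _RATE_HEIGHT_CM:
            height *= 100.0
        pat_rows.append(
            (
                pid, "male" if row.male else "female", by, bm, bd,
                row.marital_status, row.residence_zone, row.site,
                enroll, art, row.regimen, weight, height,
            )
        )

        enc_days = [enroll]
        if rng.random() < _RATE_VISIT_BEFORE_ENROLL:
            enc_days.append(enroll - int(rng.integers(5, 30)))

        # --- pharmacy dispenses ------------------------------------------
        drugs = _REGIMENS[row.regimen]
        t = 0
        while t < active_end:
            s = int(np.clip(round(rng.gamma(shape, scale)), 7, 120))
            per_drug = {d: s + int(rng.integers(0, 3)) for d in drugs}
            per_drug[drugs[int(rng.integers(0, len(drugs)))]] = s  # min is s
            if rng.random() < config.missing_dispense_qty_rate:
                per_drug[drugs[int(rng.integers(0, len(drugs)))]] = None
            for d in drugs:
                disp_rows.append((pid, art + t, d, per_drug[d]))
            enc_days.append(art + t)
            if prop >= 0.999:
                lateness = -int(rng.integers(0, 3))  # gap-free, may pick up early
            else:
                # refills are mostly on time (within the 2-day grace) with
                # occasional treatment gaps; both the gap probability and the
                # gap length grow as propensity falls
                if rng.random() < min(0.95, 1.4 * (1.0 - prop)):
                    extra = rng.gamma(2.0, (20.0 + 60.0 * (1.0 - prop)) / 2.0)
                else:
                    extra = 0.0
                lateness = int(round(extra)) + int(rng.integers(-2, 3))
            t = t + max(1, s + lateness)

        # --- CD4 results ---------------------------------------------------
        if not row.miss_baseline_cd4:
            t_b = int(rng.integers(-60, 6))
            cd4_rows.append(
                (pid, art + t_b, max(5.0, round(row.cd4_true + rng.normal(0, 25))))
            )
        follow_days = np.array([270, 455, 640, 825, 1010, 1195]) + rng.integers(
            -45, 46, 6
        )
        if row.miss_followup_cd4:
            follow_days = follow_days[follow_days > 365]
        for t_f in follow_days:
            if t_f >= active_end or rng.random() > 0.85:
                continue
            val = round(_cd4_at(float(t_f), row.cd4_true, row.fail_day, rng))
            cd4_rows.append((pid, art + int(t_f), float(val)))

        # --- self-reported adherence assessments ---------------------------
        if not row.no_self_report:
            n_a = 1 + int(rng.poisson(1.3))
            days = np.unique(rng.integers(5, 182, n_a))  # inside day offsets 0..181
            for t_a in days:
                # self-report is compressed toward high values (social
                # desirability / recall), so it carries little signal
                vas = float(np.clip(rng.normal(83.0 + 10.0 * prop, 12.0), 0.0, 100.0))
                nomd = bool(rng.random() < min(1.0, 0.68 + 0.1 * prop))
                assessor = rng.choice(
                    ["clinician", "pharmacist", "other"], p=[0.3, 0.5, 0.2]
                )
                assess_rows.append((pid, art + int(t_a), round(vas, 1), nomd, assessor))
                enc_days.append(art + int(t_a))

        # --- clinic visits -------------------------------------------------
        t_v = 30
        while t_v < active_end:
            enc_days.append(art + t_v)
            t_v += int(rng.integers(60, 120))

        # --- WHO stage IV diagnoses -----------------------------------------
        if math.isfinite(row.fail_day) and rng.random() < 0.03:
            d_day = max(190, int(row.fail_day) + int(rng.integers(-30, 31)))
            if d_day < active_end:
                diag_rows.append((pid, art + d_day, True, False))
        if rng.random() < 0.01:
            diag_rows.append((pid, art + int(rng.integers(30, 400)), True, True))

        for d in sorted(set(enc_days)):
            enc_rows.append((pid, d))

    start = pd.Timestamp(config.study_start)

    def _dates(days):
        return start + pd.to_timedelta(days, unit="D")

    patients = pd.DataFrame(
        pat_rows,
        columns=[
            "patient_id", "sex", "birth_year", "birth_month", "birth_day",
            "marital_status", "residence_zone", "site", "enrollment_date",
            "art_start_date", "regimen", "weight_kg", "height_m",
        ],
    )
    patients["enrollment_date"] = _dates(patients["enrollment_date"])
    patients["art_start_date"] = _dates(patients["art_start_date"])

    dispenses = pd.DataFrame(
        disp_rows, columns=["patient_id", "dispense_date", "drug", "days_supplied"]
    )
    dispenses["dispense_date"] = _dates(dispenses["dispense_date"])
    dispenses["days_supplied"] = dispenses["days_supplied"].astype("Float64")

    cd4 = pd.DataFrame(cd4_rows, columns=["patient_id", "sample_date", "cd4"])
    cd4["sample_date"] = _dates(cd4["sample_date"])

    assessments = pd.DataFrame(
        assess_rows,
        columns=["patient_id", "date", "vas_pct", "no_missed_doses_3d", "assessor"],
    )
    assessments["date"] = _dates(assessments["date"]) if len(assessments) else pd.to_datetime(
        pd.Series([], dtype="int64")
    )

    encounters = pd.DataFrame(enc_rows, columns=["patient_id", "date"])
    encounters["date"] = _dates(encounters["date"])

    diagnoses = pd.DataFrame(
        diag_rows, columns=["patient_id", "date", "who_stage_iv", "iris_flag"]
    )
    diagnoses["date"] = _dates(diagnoses["date"]) if len(diagnoses) else pd.to_datetime(
        pd.Series([], dtype="int64")
    )

    tables = CohortTables(patients, dispenses, cd4, assessments, encounters, diagnoses)
    for name, df in tables.items():
        sort_cols = [c for c in (TABLE_SORT.get(name) or []) if c in df.columns]
        if sort_cols:
            df.sort_values(sort_cols, inplace=True, kind="mergesort", ignore_index=True)
    return tables


TABLE_SORT = {
    "patients": ["patient_id"],
    "dispenses": ["patient_id", "dispense_date", "drug"],
    "cd4": ["patient_id", "sample_date"],
    "assessments": ["patient_id", "date"],
    "encounters": ["patient_id", "date"],
    "diagnoses": ["patient_id", "date"],
}


def ground_truth(config: SimConfig, tables: CohortTables) -> pd.DataFrame:
    """Latent propensity and true failure status aligned to a generated cohort.

    Re-derives the per-patient latent frame deterministically from ``config``
    and aligns it to the patient ids present in ``tables``. Raises
    ``KeyError`` for ids that the config could not have generated.
    """
    frame = sample_patient_frame(config)
    ids = tables.patients["patient_id"]
    unknown = set(ids) - set(frame["patient_id"])
    if unknown:
        raise KeyError(f"patient ids not generated by this config: {sorted(unknown)[:5]}")
    truth = frame.set_index("patient_id").loc[ids].reset_index()
    return truth[
        [
            "patient_id", "propensity", "p_fail", "true_failure_12m", "fail_day",
            "low_pdc", "high_cd4", "short_pre_art", "male",
        ]
    ]
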