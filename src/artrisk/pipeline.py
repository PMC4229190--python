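"""Pipeline orchestration: simulate -> clean -> adherence -> outcomes ->
fit -> evaluate, with a reproducibility manifest and table validation."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd
from numpy.random import SeedSequence

from . import __version__
from .adherence import summarize_cohort
from .cleaning import clean_tables
from .config import load_config, save_config
from .evaluation import (
    STRATEGIES,
    classification_characteristics,
    cox_standardized_adherence,
    kaplan_meier,
    log_rank_test,
    projection_grid,
)
from .io import TABLE_SCHEMAS, write_tables
from .outcomes import build_cohort_12m, build_survival_dataset
from .riskmodel import assign_risk_groups, develop_risk_model, score_cohort

STAGES = ("simulate", "clean", "adherence", "outcomes", "fit", "evaluate")


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Fan one global seed out to independent per-stage seeds (< 2**31)."""
    state = SeedSequence(seed).generate_state(len(STAGES)) % (2**31)
    return {stage: int(s) for stage, s in zip(STAGES, state)}


def _now() -> str:
    return datetime.datetime.now().isoformat(timespec="seconds")


def run_all(
    config_path: str | Path,
    workdir: str | Path,
    seed: int | None = None,
    sensitivity: bool = False,
) -> dict:
    """Run every stage in order under ``workdir``; returns the manifest.

    Any stage failure aborts with the failing stage named. The manifest is
    written to ``workdir/manifest.json``.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    config = load_config(config_path)
    if seed is not None:
        config.seed = seed
    seeds = derive_stage_seeds(config.seed)
    config.seed = seeds["simulate"]

    manifest: dict = {
        "config_hash": hashlib.sha256(Path(config_path).read_bytes()).hexdigest(),
        "software_version": __version__,
        "global_seed": seed if seed is not None else config.seed,
        "stage_seeds": seeds,
        "sensitivity": sensitivity,
        "stages": [],
        "started": _now(),
    }

    def record(stage: str, rows_in: int, rows_out: int) -> None:
        manifest["stages"].append(
            {"stage": stage, "rows_in": rows_in, "rows_out": rows_out,
             "timestamp": _now()}
        )

    stage = "simulate"
    try:
        from .synthetic_emr import generate_cohort

        tables = generate_cohort(config)
        write_tables(tables, workdir / "raw")
        save_config(config, workdir / "config.resolved.yaml")
        record(stage, config.n_patients, len(tables.patients))

        stage = "clean"
        cleaned, report = clean_tables(tables)
        write_tables(cleaned, workdir / "clean")
        report.to_frame().to_csv(workdir / "cleaning_report.csv", index=False)
        record(stage, len(tables.patients), len(cleaned.patients))

        stage = "adherence"
        summaries = summarize_cohort(
            cleaned.patients, cleaned.dispenses, cleaned.assessments
        )
        summaries.to_csv(workdir / "summaries.csv", index=False)
        record(stage, len(cleaned.patients), len(summaries))

        stage = "outcomes"
        close = config.study_close
        cohort, flow12 = build_cohort_12m(
            cleaned, summaries, close, sensitivity=sensitivity
        )
        survival, flow42 = build_survival_dataset(
            cleaned, summaries, close, sensitivity=sensitivity
        )
        cohort.to_csv(workdir / "cohort.csv", index=False)
        survival.to_csv(workdir / "survival.csv", index=False)
        pd.DataFrame([flow12]).to_csv(workdir / "flow_12m.csv", index=False)
        pd.DataFrame([flow42]).to_csv(workdir / "flow_42m.csv", index=False)
        record(stage, len(cleaned.patients), len(cohort))

        stage = "fit"
        dev = develop_risk_model(cohort, seed=seeds["fit"])
        model_doc = {
            "best_measure": dev.best_measure,
            "stepwise_selected": dev.stepwise_selected,
            "weights": dev.spec.weights,
            "thresholds": dev.spec.thresholds,
            "directions": dev.directions,
            "tertile_cuts": dev.spec.tertile_cuts,
            "validation_auc": dev.validation_auc.auc,
            "validation_auc_ci": [dev.validation_auc.ci_lo, dev.validation_auc.ci_hi],
            "auc_ci_method": dev.validation_auc.method,
            "hosmer_lemeshow": {
                "statistic": dev.hosmer_lemeshow.statistic,
                "p_value": dev.hosmer_lemeshow.p_value,
                "df": dev.hosmer_lemeshow.df,
            },
            "split_seed": dev.seed,
        }
        (workdir / "model.json").write_text(json.dumps(model_doc, indent=2))
        dev.screening.to_csv(workdir / "screening.csv", index=False)
        scores = pd.concat(
            [
                pd.DataFrame(
                    {
                        "patient_id": cohort.loc[dev.derivation_index, "patient_id"],
                        "score": dev.derivation_scores,
                        "risk_group": dev.derivation_groups,
                        "split": "derivation",
                    }
                ),
                pd.DataFrame(
                    {
                        "patient_id": cohort.loc[dev.validation_index, "patient_id"],
                        "score": dev.validation_scores,
                        "risk_group": dev.validation_groups,
                        "split": "validation",
                    }
                ),
            ]
        )
        scores.to_csv(workdir / "scores.csv", index=False)
        record(stage, len(cohort), len(scores))

        stage = "evaluate"
        outdir = workdir / "report"
        outdir.mkdir(exist_ok=True)
        valid = cohort.loc[dev.validation_index]
        chars = {
            s: classification_characteristics(
                dev.validation_groups, valid["failed"], s
            )
            for s in STRATEGIES
        }
        pd.DataFrame(
            [
                {
                    "strategy": c.strategy,
                    "sensitivity": c.sensitivity,
                    "specificity": c.specificity,
                    "ppv": c.ppv,
                    "npv": c.npv,
                    "correctly_classified": c.correctly_classified,
                }
                for c in chars.values()
            ]
        ).to_csv(outdir / "characteristics.csv", index=False)
        prevalence = float(valid["failed"].mean())
        projection_grid(chars, 1000, prevalence, 500).to_csv(
            outdir / "projections.csv", index=False
        )

        surv = survival.copy()
        surv["score"] = score_cohort(dev.spec, surv)
        surv["risk_group"], _ = assign_risk_groups(
            surv["score"], dev.derivation_scores
        )
        curves = kaplan_meier(surv)
        pd.concat([c.to_frame() for c in curves.values()]).to_csv(
            outdir / "km.csv", index=False
        )
        lr = log_rank_test(surv)
        (outdir / "logrank.json").write_text(
            json.dumps(
                {"chi_square": lr.chi_square, "df": lr.df, "p_value": lr.p_value}
            )
        )
        cox_standardized_adherence(surv).to_csv(outdir / "cox.csv", index=False)
        record(stage, len(survival), len(surv))
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = _now()
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def validate_tables(indir: str | Path) -> pd.DataFrame:
    """Schema report: missing files/columns, unparseable dates, orphan ids."""
    indir = Path(indir)
    violations: list[dict] = []
    frames: dict[str, pd.DataFrame] = {}
    for name, (date_cols, required) in TABLE_SCHEMAS.items():
        path = indir / f"{name}.csv"
        if not path.exists():
            violations.append(
                {"table": name, "row": -1, "kind": "missing_file", "detail": str(path)}
            )
            continue
        df = pd.read_csv(path, dtype=str)
        frames[name] = df
        for col in required:
            if col not in df.columns:
                violations.append(
                    {"table": name, "row": -1, "kind": "missing_column", "detail": col}
                )
        for col in date_cols:
            if col not in df.columns:
                continue
            parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
            for row in df.index[parsed.isna() & df[col].notna()]:
                violations.append(
                    {
                        "table": name,
                        "row": int(row),
                        "kind": "malformed_date",
                        "detail": f"{col}={df.loc[row, col]!r}",
                    }
                )
    if "patients" in frames:
        known = set(frames["patients"]["patient_id"])
        for name, df in frames.items():
            if name == "patients" or "patient_id" not in df.columns:
                continue
            orphans = df.index[~df["patient_id"].isin(known)]
            for row in orphans:
                violations.append(
                    {
                        "table": name,
                        "row": int(row),
                        "kind": "orphan_patient_id",
                        "detail": str(df.loc[row, "patient_id"]),
                    }
                )
    return pd.DataFrame(
        violations, columns=["table", "row", "kind", "detail"]
    )
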