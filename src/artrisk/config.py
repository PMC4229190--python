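"""Simulation configuration for the synthetic EMR cohort generator.

The defaults encode the study conditions the generator emulates: a two-site
adult HIV cohort with ~21% 12-month treatment-failure prevalence, pharmacy
dispensing every ~41 days (IQR 32-50), ~40% of patients lacking any
self-reported adherence assessment, ~2% of dispenses lacking a quantity,
and a majority of patients missing baseline and/or follow-up CD4 results.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

#: Simple-model log-odds contributions of the four binary risk factors
#: (low pharmacy adherence, high baseline CD4, short pre-ART enrollment,
#: male sex), i.e. ln of odds ratios near 2.
DEFAULT_EFFECTS = {
    "low_pdc": math.log(2.16),
    "high_cd4": math.log(2.60),
    "short_pre_art": math.log(2.43),
    "male": math.log(1.87),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic EMR generator.

    All proportions are in [0, 1]. ``adherence_propensity_*`` describe the
    latent per-patient adherence propensity on [0, 1] that drives both refill
    cadence and self-report missingness. ``effect_log_odds`` gives the
    log-odds contribution of each binary risk factor to 12-month failure.
    """

    n_patients: int = 2500
    seed: int = 0
    failure_prevalence_12m: float = 0.212
    adherence_propensity_mean: float = 0.80
    adherence_propensity_sd: float = 0.16
    effect_log_odds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    dispense_days_mean: float = 40.8
    dispense_days_iqr: tuple[float, float] = (32.0, 50.0)
    missing_self_report_rate: float = 0.404
    missing_dispense_qty_rate: float = 0.02
    missing_baseline_cd4_rate: float = 0.35
    missing_followup_cd4_rate: float = 0.40
    study_start: date = date(2005, 1, 1)
    study_span_days: int = 3103  # 2005-01-01 .. 2013-06-30

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field."""
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "failure_prevalence_12m",
            "missing_self_report_rate",
            "missing_dispense_qty_rate",
            "missing_baseline_cd4_rate",
            "missing_followup_cd4_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        if not 0.0 <= self.adherence_propensity_mean <= 1.0:
            raise ValueError("adherence_propensity_mean must be in [0, 1]")
        if self.adherence_propensity_sd < 0:
            raise ValueError("adherence_propensity_sd must be >= 0")
        lo, hi = self.dispense_days_iqr
        if not lo <= hi:
            raise ValueError("dispense_days_iqr bounds must be ordered (lo <= hi)")
        if self.dispense_days_mean <= 0:
            raise ValueError("dispense_days_mean must be positive")
        if self.study_span_days < 365:
            raise ValueError("study_span_days must cover at least one year")
        unknown = set(self.effect_log_odds) - set(DEFAULT_EFFECTS)
        if unknown:
            raise ValueError(f"effect_log_odds has unknown keys: {sorted(unknown)}")

    @property
    def study_close(self) -> date:
        import datetime

        return self.study_start + datetime.timedelta(days=self.study_span_days)


def _flatten(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    effects = d.pop("effect_log_odds")
    for k, v in effects.items():
        d[f"effect_log_odds_{k}"] = float(v)
    d["dispense_days_iqr_lo"], d["dispense_days_iqr_hi"] = d.pop("dispense_days_iqr")
    d["study_start"] = cfg.study_start.isoformat()
    return d


def save_config(cfg: SimConfig, path: str | Path) -> None:
    """Write a flat key-value YAML config file."""
    Path(path).write_text(yaml.safe_dump(_flatten(cfg), sort_keys=True))


def load_config(path: str | Path) -> SimConfig:
    """Read a flat key-value YAML config file written by :func:`save_config`."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a key-value mapping")
    effects = {}
    flat = {}
    for k, v in raw.items():
        if k.startswith("effect_log_odds_"):
            effects[k[len("effect_log_odds_"):]] = float(v)
        else:
            flat[k] = v
    if "dispense_days_iqr_lo" in flat:
        flat["dispense_days_iqr"] = (
            float(flat.pop("dispense_days_iqr_lo")),
            float(flat.pop("dispense_days_iqr_hi")),
        )
    if "study_start" in flat and isinstance(flat["study_start"], str):
        flat["study_start"] = date.fromisoformat(flat["study_start"])
    known = {f.name for f in dataclasses.fields(SimConfig)}
    missing = (known - {"effect_log_odds"}) - set(flat)
    if missing:
        raise ValueError(f"config file {path} missing keys: {sorted(missing)}")
    unknown = set(flat) - known
    if unknown:
        raise ValueError(f"config file {path} has unknown keys: {sorted(unknown)}")
    cfg = SimConfig(**flat, effect_log_odds=effects or dict(DEFAULT_EFFECTS))
    cfg.validate()
    return cfg
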