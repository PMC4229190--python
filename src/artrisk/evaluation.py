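"""Risk-test characteristics, capacity-constrained targeting, survival.

Treating a risk-group cut-off as a screening test yields standard 2x2
characteristics (sensitivity, specificity, PPV, NPV, proportion correctly
classified). Those characteristics are projected onto a hypothetical
population of given size and failure prevalence, with or without a capacity
constraint on how many patients can be targeted:

* unconstrained: TP = round(sens x F), FP = round((1-spec) x NF) with
  F = round(prevalence x pop) failures and NF = pop - F non-failures;
* constrained to ``capacity`` targets: targeted = capacity and failures
  among targeted = round(PPV x capacity) (the targeted are drawn from the
  test-positives, whose failure fraction is the PPV).

Rounding is half away from zero; an exact .5 product is flagged and both
conventions (down / away-from-zero) are reported alongside.

The long-horizon evaluation works on discrete 6-month periods: Kaplan-Meier
product-limit curves by risk group, the log-rank test across groups, and
per-measure Cox screening of z-scored adherence measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

STRATEGIES = ("all_positive", "medium_plus_high", "high_only")
_POSITIVE_GROUPS = {
    "all_positive": {"low", "medium", "high"},
    "medium_plus_high": {"medium", "high"},
    "high_only": {"high"},
}


@dataclass
class RiskTestCharacteristics:
    strategy: str
    sensitivity: float
    specificity: float
    ppv: float
    npv: float          # NaN when there are no test-negatives
    correctly_classified: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


def classification_characteristics(
    groups: pd.Series, outcomes: pd.Series, strategy: str
) -> RiskTestCharacteristics:
    """2x2 screening-test characteristics for a risk-group cut-off."""
    if strategy not in _POSITIVE_GROUPS:
        raise ValueError(f"unknown strategy {strategy!r}")
    if len(groups) == 0:
        raise ValueError("empty cohort")
    pos = groups.isin(_POSITIVE_GROUPS[strategy]).to_numpy()
    y = np.asarray(outcomes).astype(bool)
    tp = int((pos & y).sum())
    fp = int((pos & ~y).sum())
    fn = int((~pos & y).sum())
    tn = int((~pos & ~y).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return RiskTestCharacteristics(
        strategy=strategy,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        correctly_classified=(tp + tn) / len(groups),
        tp=tp, fp=fp, fn=fn, tn=tn,
    )


def _round_half_away(x: float) -> int:
    x = round(x, 9)  # snap float noise so exact .5 products behave as ties
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _is_half_tie(x: float, tol: float = 1e-9) -> bool:
    return abs(x - math.floor(x) - 0.5) < tol


@dataclass
class ProjectionResult:
    strategy: str
    pop_size: int
    prevalence: float
    capacity: int | None
    targeted: int
    failures_among_targeted: int
    nonfailures_among_targeted: int
    failures_missed: int
    rounding_tie: bool = False
    failures_among_targeted_round_down: int | None = None

    def __post_init__(self):
        assert self.targeted == (
            self.failures_among_targeted + self.nonfailures_among_targeted
        )
        if self.capacity is not None:
            assert self.targeted <= self.capacity


def project_hypothetical_population(
    chars: RiskTestCharacteristics,
    pop_size: int,
    prevalence: float,
    capacity: int | None = None,
) -> ProjectionResult:
    """Project test characteristics onto a hypothetical population."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if capacity is not None and capacity > pop_size:
        raise ValueError("capacity cannot exceed the population size")
    failures = _round_half_away(prevalence * pop_size)
    nonfailures = pop_size - failures
    tie = False
    down = None
    if capacity is None:
        tp_x = chars.sensitivity * failures
        fp_x = (1.0 - chars.specificity) * nonfailures
        tp = _round_half_away(tp_x)
        fp = _round_half_away(fp_x)
        tie = _is_half_tie(tp_x) or _is_half_tie(fp_x)
        targeted = tp + fp
        if _is_half_tie(tp_x):
            down = math.floor(tp_x)
    else:
        targeted = capacity
        tp_x = chars.ppv * capacity
        tp = _round_half_away(tp_x)
        tie = _is_half_tie(tp_x)
        if tie:
            down = math.floor(tp_x)
        fp = targeted - tp
    return ProjectionResult(
        strategy=chars.strategy,
        pop_size=pop_size,
        prevalence=prevalence,
        capacity=capacity,
        targeted=targeted,
        failures_among_targeted=tp,
        nonfailures_among_targeted=fp,
        failures_missed=failures - tp,
        rounding_tie=tie,
        failures_among_targeted_round_down=down,
    )


def projection_grid(
    characteristics: dict[str, RiskTestCharacteristics],
    pop_size: int = 1000,
    prevalence: float = 0.208,
    capacity: int = 500,
) -> pd.DataFrame:
    """3 strategies x {unlimited, constrained} targeting projections."""
    rows = []
    for strategy in STRATEGIES:
        chars = characteristics[strategy]
        for cap in (None, capacity):
            needed = chars.ppv if cap is not None else (
                chars.sensitivity + chars.specificity
            )
            if math.isnan(needed):
                # degenerate strategy (no test-positives): no projection
                rows.append(
                    {
                        "strategy": strategy,
                        "capacity": "unlimited" if cap is None else cap,
                        "targeted": np.nan,
                        "failures_among_targeted": np.nan,
                        "nonfailures_among_targeted": np.nan,
                        "failures_missed": np.nan,
                        "rounding_tie": False,
                        "failures_among_targeted_round_down": np.nan,
                    }
                )
                continue
            r = project_hypothetical_population(chars, pop_size, prevalence, cap)
            rows.append(
                {
                    "strategy": strategy,
                    "capacity": "unlimited" if cap is None else cap,
                    "targeted": r.targeted,
                    "failures_among_targeted": r.failures_among_targeted,
                    "nonfailures_among_targeted": r.nonfailures_among_targeted,
                    "failures_missed": r.failures_missed,
                    "rounding_tie": r.rounding_tie,
                    "failures_among_targeted_round_down": r.failures_among_targeted_round_down,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Discrete-period survival
# --------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    group: str
    periods: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    survival: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "period": self.periods,
                "at_risk": self.at_risk,
                "events": self.events,
                "censored": self.censored,
                "survival": self.survival,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )


def kaplan_meier(
    survival_rows: pd.DataFrame,
    group_col: str = "risk_group",
    time_col: str = "period",
    event_col: str = "event",
    n_periods: int = 7,
) -> dict[str, SurvivalCurve]:
    """Product-limit curves per risk group on the discrete period grid.

    Confidence intervals use the log(-log) (exponential Greenwood) transform.
    Empty groups are omitted.
    """
    curves: dict[str, SurvivalCurve] = {}
    grid = np.arange(1, n_periods + 1)
    for grp, sub in survival_rows.groupby(group_col):
        if sub.empty:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col].astype(bool))
        tbl = kmf.event_table.reindex(grid, fill_value=0)
        # at-risk on the grid: subjects with time >= period
        t = sub[time_col].to_numpy()
        at_risk = np.array([(t >= p).sum() for p in grid])
        surv = kmf.survival_function_at_times(grid).to_numpy()
        ci = kmf.confidence_interval_survival_function_
        lo = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
        hi = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
        curves[str(grp)] = SurvivalCurve(
            group=str(grp),
            periods=grid,
            at_risk=at_risk,
            events=tbl["observed"].to_numpy(),
            censored=tbl["censored"].to_numpy(),
            survival=surv,
            ci_lo=lo,
            ci_hi=hi,
        )
    return curves


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def log_rank_test(
    survival_rows: pd.DataFrame,
    group_col: str = "risk_group",
    time_col: str = "period",
    event_col: str = "event",
) -> LogRankResult:
    """Log-rank test across risk groups on the discrete period grid."""
    groups = survival_rows[group_col]
    k = groups.nunique()
    if k < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    res = multivariate_logrank_test(
        survival_rows[time_col], groups, survival_rows[event_col].astype(bool)
    )
    return LogRankResult(
        chi_square=float(res.test_statistic), df=k - 1, p_value=float(res.p_value)
    )


def cox_standardized_adherence(
    survival_rows: pd.DataFrame,
    measures: tuple[str, ...] = ("mpr", "pdc", "tvr", "vas_mean", "pct_no_md"),
    time_col: str = "period",
    event_col: str = "event",
) -> pd.DataFrame:
    """Separate Cox fits per z-scored adherence measure; winner flagged.

    Complete-case per measure; zero-variance measures are skipped (noted in
    the output). The winner is the measure with the largest |coefficient|.
    """
    rows = []
    for m in measures:
        sub = survival_rows[[time_col, event_col, m]].dropna()
        sd = sub[m].std(ddof=1) if len(sub) > 1 else 0.0
        if len(sub) < 10 or not sd or np.isclose(sd, 0.0):
            rows.append((m, len(sub), np.nan, np.nan, np.nan, "skipped_zero_variance"))
            continue
        z = (sub[m] - sub[m].mean()) / sd
        fit_df = pd.DataFrame(
            {time_col: sub[time_col], event_col: sub[event_col].astype(int), "z": z}
        )
        cph = CoxPHFitter()
        cph.fit(fit_df, duration_col=time_col, event_col=event_col)
        coef = float(cph.params_["z"])
        se = float(cph.standard_errors_["z"])
        p = float(cph.summary.loc["z", "p"])
        rows.append((m, len(sub), coef, se, p, ""))
    out = pd.DataFrame(
        rows, columns=["measure", "n", "coef", "se", "p_value", "note"]
    )
    mags = out["coef"].abs()
    out["winner"] = mags == mags.max()
    return out
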