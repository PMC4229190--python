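"""Risk-score derivation: AUC screening, stepwise enrichment, scoring.

The development procedure mirrors standard clinical risk-score practice:

1. screen candidate adherence measures by the AUC of univariate logistic
   models on a 12-month failure outcome;
2. split the cohort 50:50 into derivation and validation halves, enrich the
   model by forward stepwise selection on AIC in the derivation half, and
   dichotomize retained continuous covariates at the decile boundary where
   predicted risk jumps;
3. turn the binary-covariate logistic coefficients into integer-like weights
   (10 x coefficient, rounded to one decimal), sum them into a risk score,
   and cut the derivation-score distribution at tertiles into low / medium /
   high groups; check calibration with the Hosmer-Lemeshow test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.random import default_rng
from scipy import stats
from sklearn.metrics import roc_auc_score

#: canonical binary risk factors and their dichotomization thresholds
DEFAULT_THRESHOLDS = {
    "pdc_max": 0.80,        # low_pdc: pdc <= 0.80
    "cd4_min": 250.0,       # high_cd4: baseline CD4 >= 250
    "pre_art_max_days": 160.0,  # short_pre_art: pre-ART enrollment <= 160 d
}

FACTOR_KEYS = ("low_pdc", "high_cd4", "short_pre_art", "male")


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows perfect separation or fails to converge."""


@dataclass
class FittedModel:
    covariates: list[str]
    design_columns: list[str]
    params: pd.Series            # includes "const"
    aic: float
    n: int
    fitted: np.ndarray           # in-sample predicted probabilities
    binary_design: bool
    llf: float
    _dummy_map: dict[str, list[str]] = field(default_factory=dict, repr=False)

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    @property
    def coefficients(self) -> pd.Series:
        return self.params.drop("const")

    def design(self, df: pd.DataFrame) -> pd.DataFrame:
        X = _build_design(df, self.covariates)[0]
        return X.reindex(columns=["const"] + self.design_columns, fill_value=0.0)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = self.design(df)
        lin = X.to_numpy() @ self.params.reindex(X.columns).to_numpy()
        return 1.0 / (1.0 + np.exp(-lin))


def _build_design(
    df: pd.DataFrame, covariates: list[str]
) -> tuple[pd.DataFrame, dict[str, list[str]], bool]:
    """Design matrix with a constant; categoricals get a missing-data category."""
    cols: dict[str, np.ndarray] = {}
    dummy_map: dict[str, list[str]] = {}
    binary = True
    for cov in covariates:
        s = df[cov]
        if s.dtype == bool or str(s.dtype) == "boolean":
            cols[cov] = s.astype(float).to_numpy()
            dummy_map[cov] = [cov]
        elif pd.api.types.is_numeric_dtype(s):
            if s.isna().any():
                raise ValueError(
                    f"numeric covariate {cov!r} has missing values; recode it "
                    "as a categorical with a missing-data category first"
                )
            vals = s.astype(float).to_numpy()
            cols[cov] = vals
            dummy_map[cov] = [cov]
            if not set(np.unique(vals)) <= {0.0, 1.0}:
                binary = False
        else:
            filled = s.astype(object).where(s.notna(), "missing").astype(str)
            levels = sorted(filled.unique())
            ref = levels[0]
            names = []
            for lev in levels[1:]:
                name = f"{cov}[{lev}]"
                cols[name] = (filled == lev).astype(float).to_numpy()
                names.append(name)
            dummy_map[cov] = names
            _ = ref
    X = pd.DataFrame(cols, index=df.index)
    X.insert(0, "const", 1.0)
    return X, dummy_map, binary


def fit_logistic(
    df: pd.DataFrame, outcome: str, covariates: list[str]
) -> FittedModel:
    """Maximum-likelihood logistic fit with explicit separation diagnostics."""
    y = df[outcome].astype(float).to_numpy()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    X, dummy_map, binary = _build_design(df, covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        # non-convergence is diagnosed explicitly below, not via warning text
        warnings.simplefilter("ignore", sm.tools.sm_exceptions.ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ) as exc:
            raise SeparationError(
                f"logistic fit failed for covariates {covariates}: {exc}"
            ) from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError(
            f"logistic fit did not converge for covariates {covariates}"
        )
    slopes = res.params.drop("const")
    if len(slopes) and np.abs(slopes.to_numpy()).max() > 15:
        raise SeparationError(
            f"implausibly large coefficients suggest separation: {covariates}"
        )
    return FittedModel(
        covariates=list(covariates),
        design_columns=[c for c in X.columns if c != "const"],
        params=res.params,
        aic=float(res.aic),
        n=len(df),
        fitted=np.asarray(res.predict(X)),
        binary_design=binary,
        llf=float(res.llf),
        _dummy_map=dummy_map,
    )


# --------------------------------------------------------------------------
# AUC with DeLong confidence interval
# --------------------------------------------------------------------------

@dataclass
class AucResult:
    auc: float
    ci_lo: float
    ci_hi: float
    n: int
    se: float
    method: str = "delong"


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def compute_auc(scores, labels, alpha: float = 0.05) -> AucResult:
    """AUC (rank statistic, ties counted half) with a DeLong-variance CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    auc = float(roc_auc_score(labels, scores))
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tz = _midranks(np.concatenate([pos, neg]))
    tx = _midranks(pos)
    ty = _midranks(neg)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v10, ddof=1) / n if n > 1 else 0.0
    )
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    return AucResult(
        auc=auc,
        ci_lo=max(0.0, auc - z * se),
        ci_hi=min(1.0, auc + z * se),
        n=m + n,
        se=se,
    )


def split_sample(
    df: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random unstratified 50:50 split; sizes differ by at most one."""
    n = len(df)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    perm = default_rng(seed).permutation(n)
    half = n // 2
    derivation = df.iloc[np.sort(perm[:half])]
    validation = df.iloc[np.sort(perm[half:])]
    return derivation, validation


def screen_measures(
    cohort: pd.DataFrame,
    measures: tuple[str, ...] = ("mpr", "pdc", "tvr", "vas_mean", "pct_no_md"),
    outcome: str = "failed",
) -> pd.DataFrame:
    """Complete-case univariate-logistic AUC per adherence measure."""
    rows = []
    for m in measures:
        sub = cohort[[m, outcome]].dropna()
        if sub.empty or sub[outcome].nunique() < 2:
            rows.append((m, len(sub), np.nan, np.nan, np.nan))
            continue
        model = fit_logistic(sub, outcome, [m])
        res = compute_auc(model.fitted, sub[outcome].to_numpy())
        rows.append((m, res.n, res.auc, res.ci_lo, res.ci_hi))
    out = pd.DataFrame(rows, columns=["measure", "n", "auc", "ci_lo", "ci_hi"])
    out["winner"] = out["auc"] == out["auc"].max()
    out["significant"] = out["ci_lo"] > 0.5
    return out


def forward_stepwise_aic(
    df: pd.DataFrame,
    outcome: str,
    forced: list[str],
    candidates: list[str],
) -> tuple[FittedModel, list[str]]:
    """Forward selection from ``forced``, adding the largest AIC improvement.

    Categorical candidates enter as whole blocks (all dummy levels at once).
    Candidates whose fit fails (separation) are skipped. Stops when no
    candidate decreases AIC. Returns the final model and the selected
    candidate names in entry order.
    """
    current = fit_logistic(df, outcome, forced)
    selected: list[str] = []
    remaining = list(candidates)
    while remaining:
        best_aic = current.aic
        best = None
        for cand in remaining:
            try:
                trial = fit_logistic(df, outcome, forced + selected + [cand])
            except SeparationError:
                continue
            if trial.aic < best_aic:
                best_aic = trial.aic
                best = (cand, trial)
        if best is None:
            break
        cand, current = best
        selected.append(cand)
        remaining.remove(cand)
    return current, selected


@dataclass
class DecileThreshold:
    covariate: str
    threshold: float
    jump: float                 # change in failure proportion at the boundary
    table: pd.DataFrame         # per-bin n, failure proportion
    fallback_distinct: bool = False


def dichotomize_by_decile_risk(
    df: pd.DataFrame, outcome: str, covariate: str
) -> DecileThreshold:
    """Decile-bin the covariate; pick the boundary with the largest risk jump."""
    sub = df[[covariate, outcome]].dropna()
    x = sub[covariate]
    fallback = x.nunique() < 10
    if fallback:
        bins = pd.Series(pd.Categorical(x), index=sub.index)
    else:
        bins = pd.qcut(x, 10, duplicates="drop")
    tab = (
        sub.groupby(bins, observed=True)[outcome]
        .agg(n="size", failure_rate="mean")
        .reset_index(names="bin")
    )
    rates = tab["failure_rate"].to_numpy()
    if len(rates) < 2:
        raise ValueError(f"covariate {covariate!r} has a single bin")
    jumps = np.diff(rates)
    k = int(np.argmax(np.abs(jumps)))
    b = tab["bin"].iloc[k]
    threshold = float(b.right) if isinstance(b, pd.Interval) else float(b)
    return DecileThreshold(
        covariate=covariate,
        threshold=threshold,
        jump=float(jumps[k]),
        table=tab,
        fallback_distinct=fallback,
    )


# --------------------------------------------------------------------------
# Risk score
# --------------------------------------------------------------------------

def _round_half_away(x: float, ndigits: int = 1) -> float:
    f = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * f + 0.5), x) / f


@dataclass
class RiskScoreSpec:
    """Weights and thresholds of the derived additive risk score."""

    weights: dict[str, float]
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    tertile_cuts: tuple[float, float] | None = None

    @property
    def max_score(self) -> float:
        return round(sum(self.weights.values()), 10)

    def indicators(self, row: dict) -> dict[str, bool]:
        """Binary risk factors from raw covariates; missing counts as absent."""
        pdc = row.get("pdc")
        cd4 = row.get("baseline_cd4")
        pre = row.get("pre_art_days")
        male = row.get("male")
        return {
            "low_pdc": (pdc is not None and not pd.isna(pdc))
            and pdc <= self.thresholds["pdc_max"],
            "high_cd4": (cd4 is not None and not pd.isna(cd4))
            and cd4 >= self.thresholds["cd4_min"],
            "short_pre_art": (pre is not None and not pd.isna(pre))
            and pre <= self.thresholds["pre_art_max_days"],
            "male": bool(male) if male is not None and not pd.isna(male) else False,
        }


def build_risk_score(
    model: FittedModel,
    thresholds: dict[str, float] | None = None,
) -> RiskScoreSpec:
    """Weights = round(10 x coefficient, 1) from a binary-covariate model."""
    if not model.binary_design:
        raise ValueError("risk-score weights require an all-binary design")
    weights = {
        name: _round_half_away(10.0 * float(coef), 1)
        for name, coef in model.coefficients.items()
    }
    return RiskScoreSpec(
        weights=weights, thresholds=dict(thresholds or DEFAULT_THRESHOLDS)
    )


def apply_risk_score(spec: RiskScoreSpec, covariates: dict | pd.Series) -> float:
    """Sum of weights whose risk indicator is true for this patient."""
    row = dict(covariates)
    ind = spec.indicators(row)
    score = 0.0
    for key, w in spec.weights.items():
        flag = ind.get(key)
        if flag is None:
            # weight named after a design column already carrying 0/1
            flag = bool(row.get(key, False))
        score += w * bool(flag)
    return round(score, 10)


def score_cohort(spec: RiskScoreSpec, cohort: pd.DataFrame) -> pd.Series:
    return cohort.apply(
        lambda r: apply_risk_score(spec, r), axis=1
    ).astype(float)


def assign_risk_groups(
    scores: pd.Series | np.ndarray, derivation_scores: pd.Series | np.ndarray
) -> tuple[pd.Series, tuple[float, float]]:
    """Low/medium/high by tertiles of the derivation-score distribution.

    Ties at a cut go to the lower group; validation scores are classified
    with the derivation cuts.
    """
    deriv = np.asarray(derivation_scores, dtype=float)
    if len(deriv) == 0:
        raise ValueError("derivation scores must be non-empty")
    c1, c2 = np.quantile(deriv, [1 / 3, 2 / 3])
    if len(np.unique(deriv)) < 3:
        warnings.warn("degenerate risk-score distribution; groups may collapse")
    s = pd.Series(np.asarray(scores, dtype=float))
    groups = pd.Series(
        np.where(s <= c1, "low", np.where(s <= c2, "medium", "high")),
        index=s.index,
        dtype="object",
    )
    if isinstance(scores, pd.Series):
        groups.index = scores.index
    return groups, (float(c1), float(c2))


@dataclass
class RiskModelDevelopment:
    """Everything the three-step development produces."""

    screening: pd.DataFrame
    best_measure: str
    stepwise_selected: list[str]
    thresholds: dict[str, float]
    directions: dict[str, str]          # factor -> "le" / "ge"
    dropped_factors: list[str]          # degenerate indicators shed from the score
    model: FittedModel
    spec: RiskScoreSpec
    derivation_index: pd.Index
    validation_index: pd.Index
    derivation_scores: pd.Series
    validation_scores: pd.Series
    validation_groups: pd.Series
    derivation_groups: pd.Series
    validation_auc: AucResult
    hosmer_lemeshow: "HosmerLemeshowResult"
    seed: int


_CONTINUOUS_FACTORS = {
    # continuous column -> (factor key, canonical direction)
    "pdc": ("low_pdc", "le"),
    "baseline_cd4": ("high_cd4", "ge"),
    "pre_art_days": ("short_pre_art", "le"),
}


def develop_risk_model(
    cohort: pd.DataFrame,
    seed: int,
    outcome: str = "failed",
    candidates: list[str] | None = None,
) -> RiskModelDevelopment:
    """Run the full three-step development on a 12-month cohort.

    Complete-case on the screened measure; the stepwise runs on the
    derivation half with the winning adherence measure forced in.
    """
    screening = screen_measures(cohort, outcome=outcome)
    best = screening.loc[screening["winner"], "measure"].iloc[0]

    work = cohort.dropna(subset=[best, "baseline_cd4", "pre_art_days"]).copy()
    work[outcome] = work[outcome].astype(int)
    derivation, validation = split_sample(work, seed)
    derivation = derivation.copy()
    validation = validation.copy()

    if candidates is None:
        candidates = [
            "male", "baseline_cd4", "pre_art_days", "age_at_art_start",
            "site", "marital_status", "residence_zone", "regimen",
            "n_assessments", "any_clinician_assessment",
        ]
    candidates = [
        c
        for c in candidates
        if c in work.columns
        and not (pd.api.types.is_numeric_dtype(work[c]) and work[c].isna().any())
    ]
    _, selected = forward_stepwise_aic(derivation, outcome, [best], candidates)

    # dichotomize the retained continuous covariates (and the measure itself)
    thresholds: dict[str, float] = {}
    directions: dict[str, str] = {}
    factors: list[str] = []
    for col in [best] + selected:
        if col in _CONTINUOUS_FACTORS or (
            col not in ("male",)
            and pd.api.types.is_numeric_dtype(work[col])
            and work[col].nunique() > 2
        ):
            key, default_dir = _CONTINUOUS_FACTORS.get(col, (f"{col}_bin", "ge"))
            dt = dichotomize_by_decile_risk(derivation, outcome, col)
            # orient the indicator toward the side with higher observed risk
            above = derivation.loc[derivation[col] >= dt.threshold, outcome].mean()
            below = derivation.loc[derivation[col] < dt.threshold, outcome].mean()
            if pd.isna(above) or pd.isna(below) or above == below:
                direction = default_dir
            else:
                direction = "ge" if above > below else "le"
            thresholds[key] = dt.threshold
            directions[key] = direction
            for half in (derivation, validation, work):
                half[key] = (
                    half[col] >= dt.threshold
                    if direction == "ge"
                    else half[col] <= dt.threshold
                )
            factors.append(key)
        elif work[col].dtype == bool or set(work[col].dropna().unique()) <= {0, 1}:
            factors.append(col)
        # multi-level categoricals stay in the selection report but cannot
        # enter the additive score; the final simple model is binary-only
    for df_ in (derivation, validation, work):
        for f in factors:
            df_[f] = df_[f].astype(bool)

    # indicators that never vary in the derivation half carry no information
    # and would make the design singular
    dropped = [f for f in factors if derivation[f].nunique() < 2]
    factors = [f for f in factors if f not in dropped]
    if not factors:
        raise SeparationError(
            "no usable binary factor varies in the derivation sample"
        )
    while True:
        try:
            model = fit_logistic(derivation, outcome, factors)
            break
        except SeparationError:
            if len(factors) == 1:
                raise
            # shed the most lopsided indicator and retry
            worst = min(
                factors, key=lambda f: min(
                    derivation[f].mean(), 1 - derivation[f].mean()
                )
            )
            dropped.append(worst)
            factors = [f for f in factors if f != worst]
    spec = build_risk_score(model)
    spec.thresholds = {
        "pdc_max": thresholds.get("low_pdc", DEFAULT_THRESHOLDS["pdc_max"]),
        "cd4_min": thresholds.get("high_cd4", DEFAULT_THRESHOLDS["cd4_min"]),
        "pre_art_max_days": thresholds.get(
            "short_pre_art", DEFAULT_THRESHOLDS["pre_art_max_days"]
        ),
    }

    deriv_scores = pd.Series(
        derivation[factors].astype(float).to_numpy()
        @ np.array([spec.weights[f] for f in factors]),
        index=derivation.index,
    )
    valid_scores = pd.Series(
        validation[factors].astype(float).to_numpy()
        @ np.array([spec.weights[f] for f in factors]),
        index=validation.index,
    )
    deriv_groups, cuts = assign_risk_groups(deriv_scores, deriv_scores)
    valid_groups, _ = assign_risk_groups(valid_scores, deriv_scores)
    spec.tertile_cuts = cuts

    valid_pred = model.predict(validation)
    val_auc = compute_auc(valid_pred, validation[outcome].to_numpy())
    hl = hosmer_lemeshow(
        np.clip(valid_pred, 1e-9, 1 - 1e-9), validation[outcome].to_numpy()
    )
    return RiskModelDevelopment(
        screening=screening,
        best_measure=best,
        stepwise_selected=selected,
        thresholds=thresholds,
        directions=directions,
        dropped_factors=dropped,
        model=model,
        spec=spec,
        derivation_index=derivation.index,
        validation_index=validation.index,
        derivation_scores=deriv_scores,
        validation_scores=valid_scores,
        validation_groups=valid_groups,
        derivation_groups=deriv_groups,
        validation_auc=val_auc,
        hosmer_lemeshow=hl,
        seed=seed,
    )


@dataclass
class HosmerLemeshowResult:
    statistic: float
    p_value: float
    df: int
    table: pd.DataFrame
    merged_groups: int = 0


def hosmer_lemeshow(
    predicted, observed, g: int = 10
) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow goodness of fit on g predicted-risk quantile groups."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    order = np.argsort(p, kind="mergesort")
    idx_groups = [ix for ix in np.array_split(order, g) if len(ix)]
    merged = g - len(idx_groups)
    # merge groups whose expected count degenerates into their neighbour
    final: list[np.ndarray] = []
    pending: np.ndarray | None = None
    for ix in idx_groups:
        if pending is not None:
            ix = np.concatenate([pending, ix])
            pending = None
        e = p[ix].sum()
        if e * (1.0 - e / len(ix)) <= 0:
            pending = ix
            merged += 1
            continue
        final.append(ix)
    if pending is not None:
        if final:
            final[-1] = np.concatenate([final[-1], pending])
        else:
            final = [pending]
    stat = 0.0
    rows = []
    for ix in final:
        n_g = len(ix)
        e = p[ix].sum()
        o = y[ix].sum()
        denom = e * (1.0 - e / n_g)
        if denom > 0:
            stat += (o - e) ** 2 / denom
        rows.append((n_g, o, e))
    table = pd.DataFrame(rows, columns=["n", "observed", "expected"])
    df_ = max(1, len(rows) - 2)
    return HosmerLemeshowResult(
        statistic=float(stat),
        p_value=float(stats.chi2.sf(stat, df_)),
        df=df_,
        table=table,
        merged_groups=merged,
    )
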