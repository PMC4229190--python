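"""Derive the risk score: AUC screening, 50:50 split, forward-AIC
enrichment, decile dichotomization, weight construction, tertile groups."""

import json
from pathlib import Path

import pandas as pd

from artrisk.riskmodel import develop_risk_model

REPO = Path(__file__).resolve().parents[1]
ROOT = REPO / "results" / "analysis"
DATA = REPO / "scratch" / "emr"


def main() -> None:
    cohort = pd.read_csv(DATA / "cohort.csv")
    dev = develop_risk_model(cohort, seed=20260926)

    dev.screening.to_csv(ROOT / "screening.csv", index=False)
    doc = {
        "best_measure": dev.best_measure,
        "stepwise_selected": dev.stepwise_selected,
        "weights": dev.spec.weights,
        "thresholds": dev.spec.thresholds,
        "directions": dev.directions,
        "tertile_cuts": dev.spec.tertile_cuts,
        "validation_auc": dev.validation_auc.auc,
        "validation_auc_ci": [dev.validation_auc.ci_lo, dev.validation_auc.ci_hi],
        "hosmer_lemeshow_p": dev.hosmer_lemeshow.p_value,
        "split_seed": dev.seed,
    }
    (ROOT / "model.json").write_text(json.dumps(doc, indent=2))
    scores = pd.concat(
        [
            pd.DataFrame({
                "patient_id": cohort.loc[dev.derivation_index, "patient_id"],
                "score": dev.derivation_scores,
                "risk_group": dev.derivation_groups,
                "split": "derivation",
            }),
            pd.DataFrame({
                "patient_id": cohort.loc[dev.validation_index, "patient_id"],
                "score": dev.validation_scores,
                "risk_group": dev.validation_groups,
                "split": "validation",
            }),
        ]
    )
    scores.to_csv(DATA / "scores.csv", index=False)

    print("measure screening (univariate logistic AUC):")
    print(dev.screening.to_string(index=False))
    print(f"stepwise additions beyond {dev.best_measure}: {dev.stepwise_selected}")
    print(f"score weights: {dev.spec.weights}")
    print(f"dichotomization thresholds: {dev.spec.thresholds}")
    print(f"tertile cuts: {dev.spec.tertile_cuts}")
    print(f"validation AUC: {dev.validation_auc.auc:.3f} "
          f"({dev.validation_auc.ci_lo:.3f}, {dev.validation_auc.ci_hi:.3f}); "
          f"Hosmer-Lemeshow p = {dev.hosmer_lemeshow.p_value:.3f}")


if __name__ == "__main__":
    main()
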