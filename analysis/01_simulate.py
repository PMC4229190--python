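"""Generate the synthetic EMR cohort used by the downstream analyses.

Writes the six raw tables (patients, dispenses, cd4, assessments,
encounters, diagnoses) plus the resolved config under results/analysis/raw.
"""

from pathlib import Path

from artrisk.config import SimConfig, save_config
from artrisk.io import write_tables
from artrisk.synthetic_emr import generate_cohort, ground_truth

REPO = Path(__file__).resolve().parents[1]
ROOT = REPO / "results" / "analysis"
DATA = REPO / "scratch" / "emr"  # bulky intermediate tables


def main() -> None:
    cfg = SimConfig(n_patients=2500, seed=20260926)
    tables = generate_cohort(cfg)
    out = DATA / "raw"
    write_tables(tables, out)
    save_config(cfg, out / "config.resolved.yaml")
    ROOT.mkdir(parents=True, exist_ok=True)
    truth = ground_truth(cfg, tables)
    truth.to_csv(DATA / "ground_truth.csv", index=False)
    print(f"simulated {len(tables.patients)} patients "
          f"({len(tables.dispenses)} dispense rows, {len(tables.cd4)} CD4 results)")
    print(f"latent 12-month failure prevalence: "
          f"{truth['true_failure_12m'].mean():.3f} "
          f"(configured {cfg.failure_prevalence_12m})")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
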