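"""Compute the five first-6-months adherence measures for every patient."""

from pathlib import Path

from artrisk.adherence import summarize_cohort
from artrisk.io import read_tables

REPO = Path(__file__).resolve().parents[1]
ROOT = REPO / "results" / "analysis"
DATA = REPO / "scratch" / "emr"


def main() -> None:
    tables = read_tables(DATA / "clean")
    summaries = summarize_cohort(
        tables.patients, tables.dispenses, tables.assessments
    )
    summaries.to_csv(DATA / "summaries.csv", index=False)
    n = len(summaries)
    print(f"adherence summaries for {n} patients -> {DATA / 'summaries.csv'}")
    for m in ("mpr", "pdc", "tvr", "vas_mean", "pct_no_md"):
        avail = summaries[m].notna()
        print(f"  {m}: available {avail.sum()}/{n} "
              f"({100 * (1 - avail.mean()):.1f}% missing), "
              f"mean {summaries[m].mean():.3f}")


if __name__ == "__main__":
    main()
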