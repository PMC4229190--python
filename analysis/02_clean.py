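"""Apply the data-cleaning rules to the raw tables and report what changed."""

from pathlib import Path

from artrisk.cleaning import clean_tables
from artrisk.io import read_tables, write_tables

REPO = Path(__file__).resolve().parents[1]
ROOT = REPO / "results" / "analysis"
DATA = REPO / "scratch" / "emr"


def main() -> None:
    tables = read_tables(DATA / "raw")
    cleaned, report = clean_tables(tables)
    write_tables(cleaned, DATA / "clean")
    report.to_frame().to_csv(ROOT / "cleaning_report.csv", index=False)
    print("cleaning rule counts:")
    for rule, n in sorted(report.counts.items()):
        print(f"  {rule}: {n}")
    print(f"cleaned tables written to {DATA / 'clean'}")


if __name__ == "__main__":
    main()
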