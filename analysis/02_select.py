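#!/usr/bin/env python
"""Run the record-selection cascade and print the inclusion table.

Mirrors the original study's data-cleaning stages: age window 1-138 d,
farm recording span > 365 d, removal of estimated weights, injection of
confirmed birth weights at age 0, and weight bounds (30, 225] kg.
"""

from pathlib import Path

from calfgrowth.records import read_records, write_records
from calfgrowth.selection import run_selection

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_records(OUT / "records.csv")
    selected, report = run_selection(records)
    write_records(selected, OUT / "selected.csv")
    frame = report.to_frame()
    frame.to_csv(OUT / "selection_report.csv", index=False)
    print(frame.to_string(index=False))
    print(f"\nretained {len(selected)} of {len(records)} recordings")


if __name__ == "__main__":
    main()
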