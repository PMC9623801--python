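#!/usr/bin/env python
"""Simulate a desk-scale calf-weight population with realistic defects.

Generates 10 practices / 60 farms / 3,000 calves from the published
generating values, with every corruption class injected at a low rate,
and writes the record table plus ground truth under results/.
"""

from pathlib import Path

from calfgrowth.records import write_records
from calfgrowth.synthetic import CorruptionConfig, desk_config, simulate_population

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = desk_config(
        corruption=CorruptionConfig(
            age_implausible=0.03,
            estimate_flag=0.05,
            weight_out_of_range=0.02,
            short_window_farm=0.1,
        ),
        seed=20251001,
    )
    records, truth = simulate_population(config)
    OUT.mkdir(exist_ok=True)
    write_records(records, OUT / "records.csv")
    truth.save(OUT / "truth.json")
    print(f"wrote {len(records)} records for "
          f"{records['calf_id'].nunique()} calves on "
          f"{records['farm_id'].nunique()} farms")
    print("injected defects:", truth.corruption_tallies)


if __name__ == "__main__":
    main()
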