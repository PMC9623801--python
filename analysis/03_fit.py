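#!/usr/bin/env python
"""Fit the three-level random-slope model by Gibbs sampling.

Uses the desk schedule (5,000 burn-in, 50,000 iterations, thin 10 ->
5,000 stored draws); the production schedule of the original analysis
(100,000 / 1,000,000 / 100) is available via McmcSettings.production().
Writes the thinned chain and posterior summaries under results/.
"""

from pathlib import Path

from calfgrowth.model import McmcSettings, build_design, run_mcmc
from calfgrowth.records import read_records

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_records(OUT / "selected.csv")
    design = build_design(records)
    print(f"design: {design.n_records} records, {design.n_farms} farms, "
          f"{design.n_practices} practices")
    chain = run_mcmc(design, settings=McmcSettings.desk(seed=20251001))
    chain.save(OUT)
    summary = chain.params.describe().loc[["mean", "std"]].T
    summary.to_csv(OUT / "posterior_summary.csv")
    print(summary.to_string())


if __name__ == "__main__":
    main()
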