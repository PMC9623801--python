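#!/usr/bin/env python
"""Chain diagnostics: ESS and Raftery-Lewis for the variance
parameters, plus the conditional DIC of the fitted model."""

from pathlib import Path

import pandas as pd

from calfgrowth.diagnostics import dic, effective_sample_size, raftery_lewis
from calfgrowth.model import PosteriorChain, build_design
from calfgrowth.records import read_records

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    chain = PosteriorChain.load(OUT)
    rows = []
    for name in ("var_practice", "var_farm_int", "var_farm_slope",
                 "var_residual"):
        series = chain.params[name].to_numpy()
        rl = raftery_lewis(series)
        rows.append(
            {
                "parameter": name,
                "ess": round(effective_sample_size(series)),
                "rl_n_required": rl.n_required,
                "rl_n_min": rl.n_min,
                "rl_burn_in": rl.burn_in_required,
                "rl_dependence": round(rl.dependence_factor, 2),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "diagnostics.csv", index=False)
    print(table.to_string(index=False))

    design = build_design(read_records(OUT / "selected.csv"))
    res = dic(chain, design)
    print(f"\nDIC = {res.dic:.1f}  (pD = {res.p_d:.1f}, "
          f"mean deviance = {res.mean_deviance:.1f})")
    (OUT / "dic.txt").write_text(
        f"dic {res.dic:.3f}\np_d {res.p_d:.3f}\n"
        f"mean_deviance {res.mean_deviance:.3f}\n"
    )


if __name__ == "__main__":
    main()
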