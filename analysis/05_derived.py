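#!/usr/bin/env python
"""Derived quantities from the fitted chain, next to the published
values of the original study for orientation.

Writes the VPC-by-age table, growth summaries, cluster coverage and the
two figures (VPC boxplots by age; the fan of farm growth curves).
"""

from pathlib import Path

import pandas as pd

from calfgrowth import plots, reference
from calfgrowth.derived import (
    cluster_mean_coverage,
    cumulative_growth_rate,
    gaussian_cluster_interval,
    growth_rate,
    growth_summary,
    plug_in_vpc,
    vpc_profile,
)
from calfgrowth.model import PosteriorChain

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    chain = PosteriorChain.load(OUT)
    profile = vpc_profile(chain)
    profile.check_normalization()
    profile.summary.to_csv(OUT / "vpc_profile.csv", index=False)

    growth = growth_summary(chain)
    growth.to_csv(OUT / "growth_summary.csv", index=False)
    coverage = pd.concat(
        [
            cluster_mean_coverage(chain, "birth_weight"),
            cluster_mean_coverage(chain, "cumulative_rate"),
        ]
    )
    coverage.to_csv(OUT / "cluster_coverage.csv", index=False)

    plots.plot_vpc_boxplots(profile, OUT / "vpc_boxplots.png")
    plots.plot_farm_growth_fan(chain, OUT / "growth_fan.png")

    published = reference.published_parameter_means()
    print("fitted (this chain) vs original study, derived quantities:")
    for age in (0, 130):
        fit_vpc = profile.summary.query(f"age_days == {age}")
        fit_farm = float(fit_vpc.loc[fit_vpc.level == 'farm', 'mean'].iloc[0])
        pub_farm = plug_in_vpc(published, age)["farm"]
        print(f"  farm VPC at {age:>3} d: {fit_farm:.2f}  (study: {pub_farm:.2f})")
    g1 = growth.query("quantity == 'cumulative_rate_to_138d'")["mean"].iloc[0]
    print(f"  cumulative rate to 138 d: {g1:.2f} kg/d "
          f"(study: {cumulative_growth_rate(published, 138):.2f})")
    lo, hi = gaussian_cluster_interval(published, "birth_weight")
    fit_lo, fit_hi = coverage["mean"].iloc[0], coverage["mean"].iloc[1]
    print(f"  birth-weight cluster coverage: ({fit_lo:.0f}, {fit_hi:.0f}) kg "
          f"(study: ({lo:.0f}, {hi:.0f}))")
    g_at_1 = growth.loc[
        growth["quantity"] == "growth_rate_at_1d", "mean"
    ].iloc[0]
    print(f"  growth rate at 1 d: {g_at_1:.2f} kg/d "
          f"(study: {growth_rate(published, 1):.2f})")


if __name__ == "__main__":
    main()
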