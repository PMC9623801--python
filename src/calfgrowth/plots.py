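"""Plots: VPC-by-age boxplots and the fan of farm-specific growth curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from calfgrowth.derived import VPCProfile
from calfgrowth.model import PosteriorChain


def plot_vpc_boxplots(
    profile: VPCProfile, path: str | Path, age_step: int = 10
) -> None:
    """Boxplots of posterior VPC draws by age, one panel per level."""
    ages = profile.ages
    sel = np.arange(0, ages.size, age_step)
    fig, axes = plt.subplots(3, 1, figsize=(9, 9), sharex=True)
    for ax, level in zip(axes, ("practice", "farm", "calf")):
        data = [profile.draws[level][:, i] for i in sel]
        ax.boxplot(data, tick_labels=[f"{ages[i]:.0f}" for i in sel],
                   whis=(2.5, 97.5), flierprops={"markersize": 1})
        ax.set_ylabel(f"VPC ({level})")
        ax.set_ylim(0, 1)
    axes[-1].set_xlabel("calf age (days)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_farm_growth_fan(
    chain: PosteriorChain, path: str | Path, horizon: int = 138
) -> None:
    """Mean growth curve with a fan of cluster-specific curves.

    Farm curves are drawn from the posterior-mean fixed effects and the
    posterior-mean farm effects when available; otherwise sampled from
    the posterior-mean covariance components.
    """
    means = chain.posterior_means()
    ages = np.arange(0, horizon + 1, dtype=float)
    mu = means["alpha"] + means.get("beta_age", 0.0) * ages
    mu = mu + means.get("beta_age2", 0.0) * ages**2

    fig, ax = plt.subplots(figsize=(8, 5))
    if chain.posterior_mean_u is not None:
        u = chain.posterior_mean_u
        v = (
            chain.posterior_mean_v[chain.farm_practice]
            if chain.posterior_mean_v is not None
            else np.zeros(len(u))
        )
        for j in range(len(u)):
            ax.plot(
                ages, mu + v[j] + u[j, 0] + u[j, 1] * ages,
                color="grey", alpha=0.35, lw=0.7,
            )
    ax.plot(ages, mu, color="black", lw=2.5, label="population mean curve")
    ax.set_xlabel("calf age (days)")
    ax.set_ylabel("weight (kg)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
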