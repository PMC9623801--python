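"""Derived quantities from a fitted chain: variance partition, growth,
cluster coverage and posterior predictive weights.

With a random slope for age at the farm level, the farm-level variance
is a quadratic function of age,

    var_farm(t) = var_u0 + 2 t cov_u01 + t^2 var_u1,

while the practice variance (``var_v``) and calf-level residual
variance (``var_e``) are constant in age.  The variance partition
coefficient (VPC) of a level at age ``t`` is that level's variance
divided by the total at ``t``; the three VPCs sum to one by
construction and shift with age -- at birth most unexplained variance
sits between calves, while from mid-rearing onwards the farm level
dominates.

Growth rates follow from the quadratic mean curve
``mu(t) = alpha + beta1 t + beta2 t^2``: the instantaneous rate is
``beta1 + 2 beta2 t`` and the cumulative (birth-to-horizon) rate is the
chord slope ``beta1 + beta2 h``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from calfgrowth.model import PosteriorChain

_LEVELS = ("practice", "farm", "calf")


# ---------------------------------------------------------------------------
# per-draw variance functions
# ---------------------------------------------------------------------------


def variance_at_age(
    components: Mapping[str, float], age: float
) -> dict[str, float]:
    """Per-level variances (kg^2) at one age for one draw's components.

    ``components`` is keyed like the chain columns: ``var_practice``,
    ``var_farm_int``, ``cov_farm_int_slope``, ``var_farm_slope``,
    ``var_residual``.
    """
    farm = (
        components["var_farm_int"]
        + 2.0 * age * components["cov_farm_int_slope"]
        + age**2 * components["var_farm_slope"]
    )
    if farm < 0:
        raise AssertionError(
            f"farm variance {farm:.4g} at age {age} is negative; "
            "the farm covariance matrix is not positive definite"
        )
    return {
        "practice": float(components["var_practice"]),
        "farm": float(farm),
        "calf": float(components["var_residual"]),
    }


def plug_in_vpc(components: Mapping[str, float], age: float) -> dict[str, float]:
    """VPC per level at one age from one set of variance components."""
    var = variance_at_age(components, age)
    total = sum(var.values())
    return {level: var[level] / total for level in _LEVELS}


# ---------------------------------------------------------------------------
# posterior VPC profile
# ---------------------------------------------------------------------------


@dataclass
class VPCProfile:
    """Posterior VPC draws and summaries over an age grid.

    ``draws`` maps level name to an array of shape (n_draws, n_ages).
    ``summary`` is tidy: one row per (age, level) with the posterior
    mean, median and 0.025/0.975 quantiles of the per-draw ratio, plus
    the plug-in ratio of posterior-mean components.
    """

    ages: np.ndarray
    draws: dict[str, np.ndarray]
    summary: pd.DataFrame

    def check_normalization(self) -> None:
        total = sum(self.draws[level] for level in _LEVELS)
        if not np.allclose(total, 1.0, rtol=0, atol=1e-12):
            raise AssertionError("VPC draws do not sum to 1 across levels")


def vpc_profile(
    chain: PosteriorChain, ages: np.ndarray | None = None
) -> VPCProfile:
    """VPC posterior distributions on an age grid (default 0-130 days).

    The reported point estimate is the posterior mean of the per-draw
    ratio; the plug-in ratio of posterior-mean components is carried
    alongside in the summary table.
    """
    if ages is None:
        ages = np.arange(0, 131)
    ages = np.asarray(ages, dtype=float)
    p = chain.params
    var_v = p["var_practice"].to_numpy()[:, None]
    farm = (
        p["var_farm_int"].to_numpy()[:, None]
        + 2.0 * ages[None, :] * p["cov_farm_int_slope"].to_numpy()[:, None]
        + ages[None, :] ** 2 * p["var_farm_slope"].to_numpy()[:, None]
    )
    if (farm < 0).any():
        raise AssertionError(
            "negative farm variance encountered in the chain; "
            "a stored draw is not positive definite"
        )
    var_e = p["var_residual"].to_numpy()[:, None]
    total = var_v + farm + var_e
    draws = {
        "practice": var_v / total,
        "farm": farm / total,
        "calf": var_e / total,
    }

    means = chain.posterior_means()
    rows = []
    for i, age in enumerate(ages):
        plug = plug_in_vpc(means, age)
        for level in _LEVELS:
            d = draws[level][:, i]
            rows.append(
                {
                    "age_days": age,
                    "level": level,
                    "mean": d.mean(),
                    "median": np.median(d),
                    "q025": np.quantile(d, 0.025),
                    "q975": np.quantile(d, 0.975),
                    "plug_in": plug[level],
                }
            )
    return VPCProfile(ages=ages, draws=draws, summary=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# growth rates
# ---------------------------------------------------------------------------


def growth_rate(
    fixed_effects: Mapping[str, float] | pd.DataFrame, age: float
) -> float | np.ndarray:
    """Instantaneous growth rate ``beta1 + 2 beta2 age`` (kg/day).

    Accepts one draw (mapping) or a chain parameter table (DataFrame),
    returning a scalar or per-draw array respectively.
    """
    if isinstance(fixed_effects, pd.DataFrame):
        b1 = fixed_effects["beta_age"].to_numpy()
        b2 = fixed_effects.get(
            "beta_age2", pd.Series(np.zeros(len(fixed_effects)))
        ).to_numpy()
        return b1 + 2.0 * b2 * age
    b1 = fixed_effects["beta_age"]
    b2 = fixed_effects.get("beta_age2", 0.0)
    return float(b1 + 2.0 * b2 * age)


def cumulative_growth_rate(
    fixed_effects: Mapping[str, float] | pd.DataFrame, horizon: float
) -> float | np.ndarray:
    """Chord slope of the mean curve from birth to ``horizon`` days.

    Equals ``beta1 + beta2 * horizon`` for the quadratic curve, i.e.
    ``(mu(h) - mu(0)) / h``.  A zero horizon is undefined.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if isinstance(fixed_effects, pd.DataFrame):
        b1 = fixed_effects["beta_age"].to_numpy()
        b2 = fixed_effects.get(
            "beta_age2", pd.Series(np.zeros(len(fixed_effects)))
        ).to_numpy()
        return b1 + b2 * horizon
    b1 = fixed_effects["beta_age"]
    b2 = fixed_effects.get("beta_age2", 0.0)
    return float(b1 + b2 * horizon)


def growth_summary(
    chain: PosteriorChain,
    ages: tuple[float, ...] = (1.0, 138.0),
    horizon: float = 138.0,
) -> pd.DataFrame:
    """Posterior summaries of instantaneous and cumulative growth rates."""
    rows = []
    for age in ages:
        d = growth_rate(chain.params, age)
        rows.append(_summary_row(f"growth_rate_at_{age:g}d", d))
    d = cumulative_growth_rate(chain.params, horizon)
    rows.append(_summary_row(f"cumulative_rate_to_{horizon:g}d", d))
    return pd.DataFrame(rows)


def _summary_row(name: str, draws: np.ndarray) -> dict:
    return {
        "quantity": name,
        "mean": float(np.mean(draws)),
        "median": float(np.median(draws)),
        "q025": float(np.quantile(draws, 0.025)),
        "q975": float(np.quantile(draws, 0.975)),
    }


# ---------------------------------------------------------------------------
# cluster-specific coverage
# ---------------------------------------------------------------------------


def gaussian_cluster_interval(
    components: Mapping[str, float],
    quantity: Literal["birth_weight", "cumulative_rate"] = "birth_weight",
    quantiles: tuple[float, float] = (0.025, 0.975),
    horizon: float = 138.0,
) -> tuple[float, float]:
    """Quantile interval of cluster (practice-farm) means for one draw.

    Under the model, cluster-specific mean birth weight is
    ``alpha + v_k + u0_j ~ N(alpha, var_v + var_u0)`` and the
    cluster-specific cumulative growth rate to ``horizon`` is
    ``beta1 + beta2 h + u1_j ~ N(beta1 + beta2 h, var_u1)`` (the farm
    slope is the only random contribution to the rate).
    """
    lo_q, hi_q = quantiles
    if quantity == "birth_weight":
        center = components["alpha"]
        sd = np.sqrt(
            components["var_practice"] + components["var_farm_int"]
        )
    elif quantity == "cumulative_rate":
        center = cumulative_growth_rate(components, horizon)
        sd = np.sqrt(components["var_farm_slope"])
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return (
        float(center + stats.norm.ppf(lo_q) * sd),
        float(center + stats.norm.ppf(hi_q) * sd),
    )


def cluster_mean_coverage(
    chain: PosteriorChain,
    quantity: Literal["birth_weight", "cumulative_rate"] = "birth_weight",
    quantiles: tuple[float, float] = (0.025, 0.975),
    method: Literal["gaussian", "empirical"] = "gaussian",
    horizon: float = 138.0,
) -> pd.DataFrame:
    """Posterior summary of the cluster-mean quantile interval.

    ``gaussian`` computes the interval from each draw's variance
    components under normality; ``empirical`` takes quantiles of the
    realised cluster means across the sampled farms per draw, which
    requires the chain to have stored random effects.  Returns one row
    per endpoint with posterior mean, median and a 95% credible
    interval.
    """
    lo_q, hi_q = quantiles
    if not 0.0 < lo_q < hi_q < 1.0:
        raise ValueError("quantiles must satisfy 0 < lo < hi < 1")
    if method == "gaussian":
        p = chain.params
        if quantity == "birth_weight":
            center = p["alpha"].to_numpy()
            sd = np.sqrt(
                p["var_practice"].to_numpy() + p["var_farm_int"].to_numpy()
            )
        else:
            center = np.asarray(cumulative_growth_rate(p, horizon))
            sd = np.sqrt(p["var_farm_slope"].to_numpy())
        lo = center + stats.norm.ppf(lo_q) * sd
        hi = center + stats.norm.ppf(hi_q) * sd
    elif method == "empirical":
        if chain.v_draws is None or chain.u_draws is None:
            raise ValueError(
                "empirical coverage requires a chain fitted with "
                "store_random_effects=True"
            )
        p = chain.params
        if quantity == "birth_weight":
            if chain.farm_practice is None:
                raise ValueError(
                    "chain does not carry the farm-to-practice map needed "
                    "for empirical birth-weight coverage"
                )
            # cluster mean = alpha + v_k(j) + u0_j across farms
            cluster = (
                p["alpha"].to_numpy()[:, None]
                + chain.v_draws[:, chain.farm_practice]
                + chain.u_draws[:, :, 0]
            )
        else:
            cluster = (
                np.asarray(cumulative_growth_rate(p, horizon))[:, None]
                + chain.u_draws[:, :, 1]
            )
        lo = np.quantile(cluster, lo_q, axis=1)
        hi = np.quantile(cluster, hi_q, axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(
        [
            _summary_row(f"{quantity}_q{lo_q:g}", lo),
            _summary_row(f"{quantity}_q{hi_q:g}", hi),
        ]
    )


# ---------------------------------------------------------------------------
# posterior predictive weight
# ---------------------------------------------------------------------------


def posterior_predictive_weight(
    chain: PosteriorChain,
    age: float,
    scope: Literal["median_cluster", "population"] = "median_cluster",
    quantiles: tuple[float, ...] = (0.025, 0.5, 0.975),
    intervals: tuple[tuple[float, float], ...] = (),
) -> dict:
    """Predictive weight distribution at one age, mixed over the chain.

    For each stored draw the predictive weight is Normal with mean on
    the fixed growth curve and variance ``sigma_e^2`` for the
    ``median_cluster`` scope (random effects at zero: a typical calf on
    the median farm of the median practice) or the full total variance
    at that age for the ``population`` scope.  Quantiles are of the
    posterior-mixed distribution; interval probabilities
    ``P(a < weight <= b)`` average the normal probabilities over draws.
    """
    p = chain.params
    mu = p["alpha"].to_numpy().copy()
    if "beta_age" in p:
        mu = mu + p["beta_age"].to_numpy() * age
    if "beta_age2" in p:
        mu = mu + p["beta_age2"].to_numpy() * age**2
    var = p["var_residual"].to_numpy().copy()
    if scope == "population":
        var = var + p["var_practice"].to_numpy()
        var = (
            var
            + p["var_farm_int"].to_numpy()
            + 2.0 * age * p["cov_farm_int_slope"].to_numpy()
            + age**2 * p["var_farm_slope"].to_numpy()
        )
    elif scope != "median_cluster":
        raise ValueError(f"unknown scope {scope!r}")
    sd = np.sqrt(var)

    def mix_cdf(w: np.ndarray) -> np.ndarray:
        return stats.norm.cdf(
            (np.atleast_1d(w)[:, None] - mu[None, :]) / sd[None, :]
        ).mean(axis=1)

    lo = float((mu - 8 * sd).min())
    hi = float((mu + 8 * sd).max())
    grid = np.linspace(lo, hi, 4001)
    cdf = mix_cdf(grid)
    out_q = {
        q: float(np.interp(q, cdf, grid)) for q in quantiles
    }
    probs = {}
    for a, b in intervals:
        if a > b:
            raise ValueError(f"interval ({a}, {b}) is reversed")
        pa, pb = mix_cdf(np.array([a, b]))
        probs[(a, b)] = float(pb - pa)
    return {"quantiles": out_q, "interval_probabilities": probs}
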