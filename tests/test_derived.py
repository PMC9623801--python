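"""Derived-quantity tests: variance partition arithmetic, growth rates,
cluster coverage and posterior predictive distributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from calfgrowth import reference
from calfgrowth.derived import (
    cluster_mean_coverage,
    cumulative_growth_rate,
    gaussian_cluster_interval,
    growth_rate,
    plug_in_vpc,
    posterior_predictive_weight,
    variance_at_age,
    vpc_profile,
)
from calfgrowth.model import McmcSettings, PosteriorChain, PriorSpec

PUBLISHED = reference.published_parameter_means()


def _degenerate_chain(components: dict, n_draws: int = 20, **extra):
    params = pd.DataFrame([components] * n_draws)
    return PosteriorChain(
        params=params,
        deviance=np.zeros(n_draws),
        settings=McmcSettings(burn_in=0, total_iterations=n_draws, thin=1),
        priors=PriorSpec(),
        n_records=0,
        n_farms=extra.get("n_farms", 0),
        n_practices=extra.get("n_practices", 0),
        degree=2,
        v_draws=extra.get("v_draws"),
        u_draws=extra.get("u_draws"),
        farm_practice=extra.get("farm_practice"),
    )


# ---------------------------------------------------------------------------
# variance functions and VPC
# ---------------------------------------------------------------------------


def test_variance_components_at_birth_and_130_days():
    at0 = variance_at_age(PUBLISHED, 0)
    assert at0["farm"] == pytest.approx(2.37)
    assert sum(at0.values()) == pytest.approx(98.06)
    at130 = variance_at_age(PUBLISHED, 130)
    assert at130["farm"] == pytest.approx(
        2.37 + 2 * 130 * 0.007 + 130**2 * 0.019, abs=1e-9
    )
    assert at130["farm"] == pytest.approx(325.29)


def test_zero_slope_components_give_age_constant_farm_variance():
    comps = dict(PUBLISHED, cov_farm_int_slope=0.0, var_farm_slope=0.0)
    assert variance_at_age(comps, 0)["farm"] == variance_at_age(comps, 130)["farm"]


def test_plug_in_vpc_reproduces_published_values():
    at0 = plug_in_vpc(PUBLISHED, 0)
    assert round(at0["calf"], 2) == 0.84
    assert round(at0["farm"], 2) == 0.02
    at130 = plug_in_vpc(PUBLISHED, 130)
    assert round(at130["farm"], 2) == 0.77
    assert round(at130["calf"], 2) == 0.20


def test_degenerate_chain_vpc_equals_plug_in_exactly():
    chain = _degenerate_chain(PUBLISHED)
    profile = vpc_profile(chain, ages=np.array([0.0, 60.0, 130.0]))
    profile.check_normalization()
    for _, row in profile.summary.iterrows():
        assert row["mean"] == pytest.approx(row["plug_in"], abs=1e-12)


def test_vpc_normalization_holds_exactly_on_fitted_chain(fitted):
    profile = vpc_profile(fitted["chain"])
    profile.check_normalization()
    total = sum(profile.draws[level] for level in ("practice", "farm", "calf"))
    np.testing.assert_allclose(total, 1.0, atol=1e-13)


def test_farm_vpc_grows_with_age_when_slope_variance_positive(fitted):
    profile = vpc_profile(fitted["chain"], ages=np.array([0.0, 130.0]))
    farm = profile.draws["farm"]
    assert np.all(farm[:, 1] > farm[:, 0])


def test_vpc_formula_matches_monte_carlo_variance_shares():
    # simulate random effects from one draw's components and compare
    # empirical variance shares at age 60 with the analytic partition
    rng = np.random.default_rng(12)
    n = 100_000
    age = 60.0
    v = rng.normal(0, np.sqrt(PUBLISHED["var_practice"]), n)
    chol = np.linalg.cholesky(reference.COV_FARM)
    u = rng.standard_normal((n, 2)) @ chol.T
    e = rng.normal(0, np.sqrt(PUBLISHED["var_residual"]), n)
    farm_part = u[:, 0] + u[:, 1] * age
    total = np.var(v) + np.var(farm_part) + np.var(e)
    expected = plug_in_vpc(PUBLISHED, age)
    assert np.var(farm_part) / total == pytest.approx(expected["farm"], rel=0.02)
    assert np.var(e) / total == pytest.approx(expected["calf"], rel=0.02)


# ---------------------------------------------------------------------------
# growth rates
# ---------------------------------------------------------------------------


def test_growth_rates_match_published_arithmetic():
    assert round(growth_rate(PUBLISHED, 1), 2) == 0.59
    assert round(growth_rate(PUBLISHED, 138), 2) == 0.87
    assert round(cumulative_growth_rate(PUBLISHED, 138), 2) == 0.73


def test_linear_curve_has_constant_rates():
    comps = dict(PUBLISHED, beta_age2=0.0)
    for age in (1, 60, 138):
        assert growth_rate(comps, age) == comps["beta_age"]
    assert cumulative_growth_rate(comps, 90) == comps["beta_age"]


def test_cumulative_rate_requires_positive_horizon():
    with pytest.raises(ValueError, match="horizon"):
        cumulative_growth_rate(PUBLISHED, 0)


@given(
    b1=st.floats(min_value=-2, max_value=2),
    b2=st.floats(min_value=-0.01, max_value=0.01),
    h=st.floats(min_value=1.0, max_value=400.0),
)
def test_cumulative_rate_is_the_chord_slope_of_the_curve(b1, b2, h):
    comps = {"alpha": 40.0, "beta_age": b1, "beta_age2": b2}

    def curve(t):
        return comps["alpha"] + b1 * t + b2 * t**2

    chord = (curve(h) - curve(0.0)) / h
    assert cumulative_growth_rate(comps, h) == pytest.approx(chord, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# cluster coverage
# ---------------------------------------------------------------------------


def test_gaussian_birth_weight_interval_matches_published_endpoints():
    lo, hi = gaussian_cluster_interval(PUBLISHED, "birth_weight")
    assert round(lo) == 34
    assert round(hi) == 49


def test_interval_collapses_without_cluster_variance():
    comps = dict(PUBLISHED, var_practice=0.0, var_farm_int=0.0)
    lo, hi = gaussian_cluster_interval(comps, "birth_weight")
    assert lo == hi == comps["alpha"]


def test_empirical_coverage_matches_direct_cluster_quantiles():
    rng = np.random.default_rng(21)
    J, K = 40, 8
    farm_practice = rng.integers(0, K, J)
    v = rng.normal(0, 3.0, K)
    u = rng.normal(0, [1.5, 0.1], (J, 2))
    chain = _degenerate_chain(
        PUBLISHED,
        n_draws=5,
        n_farms=J,
        n_practices=K,
        v_draws=np.tile(v, (5, 1)),
        u_draws=np.tile(u, (5, 1, 1)),
        farm_practice=farm_practice,
    )
    out = cluster_mean_coverage(chain, "birth_weight", method="empirical")
    cluster_means = PUBLISHED["alpha"] + v[farm_practice] + u[:, 0]
    assert out["mean"].iloc[0] == pytest.approx(
        np.quantile(cluster_means, 0.025)
    )
    assert out["mean"].iloc[1] == pytest.approx(
        np.quantile(cluster_means, 0.975)
    )


def test_empirical_coverage_requires_stored_effects():
    chain = _degenerate_chain(PUBLISHED)
    with pytest.raises(ValueError, match="store_random_effects"):
        cluster_mean_coverage(chain, "birth_weight", method="empirical")


# ---------------------------------------------------------------------------
# posterior predictive weight
# ---------------------------------------------------------------------------


def test_predictive_probabilities_symmetric_around_the_mean():
    chain = _degenerate_chain(PUBLISHED)
    mu = (
        PUBLISHED["alpha"]
        + PUBLISHED["beta_age"] * 60
        + PUBLISHED["beta_age2"] * 3600
    )
    out = posterior_predictive_weight(
        chain, 60, intervals=((mu - 10, mu), (mu, mu + 10))
    )
    probs = list(out["interval_probabilities"].values())
    assert probs[0] == pytest.approx(probs[1], abs=1e-9)


def test_predictive_partition_probabilities_sum_to_one():
    chain = _degenerate_chain(PUBLISHED)
    cuts = [-1e6, 50, 80, 110, 1e6]
    intervals = tuple(zip(cuts[:-1], cuts[1:]))
    out = posterior_predictive_weight(chain, 60, intervals=intervals)
    assert sum(out["interval_probabilities"].values()) == pytest.approx(1.0, abs=1e-6)


def test_degenerate_zero_variance_predictive_is_a_point_mass():
    comps = dict(
        PUBLISHED, var_residual=1e-12, var_practice=1e-12,
        var_farm_int=1e-12, cov_farm_int_slope=0.0, var_farm_slope=1e-14,
    )
    chain = _degenerate_chain(comps)
    mu = comps["alpha"] + comps["beta_age"] * 30 + comps["beta_age2"] * 900
    out = posterior_predictive_weight(chain, 30)
    for q, val in out["quantiles"].items():
        assert val == pytest.approx(mu, abs=1e-3)


def test_reversed_interval_is_rejected():
    chain = _degenerate_chain(PUBLISHED)
    with pytest.raises(ValueError, match="reversed"):
        posterior_predictive_weight(chain, 60, intervals=((80, 50),))


def test_population_scope_is_wider_than_median_cluster(fitted):
    chain = fitted["chain"]
    med = posterior_predictive_weight(chain, 100, scope="median_cluster")
    pop = posterior_predictive_weight(chain, 100, scope="population")
    med_width = med["quantiles"][0.975] - med["quantiles"][0.025]
    pop_width = pop["quantiles"][0.975] - pop["quantiles"][0.025]
    assert pop_width > med_width
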