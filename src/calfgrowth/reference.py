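"""Published posterior estimates from the original national calf-weight study.

The original analysis of the UK Calf Tracker data (28 veterinary
practices, 139 farms, 19,708 Holstein-Friesian heifer calves, 59,588
weight recordings) is the study this package re-implements.  Its raw
data are proprietary, but the published posterior means of the final
model are public and serve two roles here:

* as fixed inputs to deterministic derived-quantity arithmetic
  (variance partition coefficients, growth rates, cluster coverage),
  which can be checked against the study's published figures; and
* as generating values for the synthetic-population generator, so that
  parameter-recovery experiments run under realistic conditions.

All values are posterior means on the original scales: weights in kg,
age in days.
"""

from __future__ import annotations

import numpy as np

#: Fixed effects: intercept (kg; mean birth weight), linear age
#: coefficient (kg/day) and quadratic age coefficient (kg/day^2).
ALPHA = 41.26
BETA_AGE = 0.59
BETA_AGE2 = 0.001

#: Between-practice intercept variance (kg^2).
VAR_PRACTICE = 13.04

#: Farm-level covariance matrix of (intercept, age slope):
#: [[kg^2, kg^2/day], [kg^2/day, kg^2/day^2]].
COV_FARM = np.array([[2.37, 0.007], [0.007, 0.019]])

#: Within-calf residual variance (kg^2).
VAR_RESIDUAL = 82.65

#: The Wishart scale matrix the original fit derived from its
#: frequentist initialisation (see PriorSpec): prior precision
#: ~ Wishart_2 with 2 degrees of freedom and scale (2 * S_U)^-1.
WISHART_S_U = np.array([[4.391, 0.024], [0.024, 0.017]])

#: Hierarchy sizes of the selected study dataset.
N_PRACTICES = 28
N_FARMS = 139
N_CALVES = 19_708
N_RECORDINGS = 59_588

#: Age window (days) of retained follow-up weighings.
AGE_MIN = 1
AGE_MAX = 138

#: Weight bounds (kg): retained records satisfy 30 < w <= 225.
WEIGHT_LOWER_EXCLUSIVE = 30.0
WEIGHT_UPPER_INCLUSIVE = 225.0

#: Production MCMC schedule of the original fit.
PAPER_BURN_IN = 100_000
PAPER_ITERATIONS = 1_000_000
PAPER_THIN = 100


def published_parameter_means() -> dict[str, float]:
    """Published posterior means keyed by the chain column names."""
    return {
        "alpha": ALPHA,
        "beta_age": BETA_AGE,
        "beta_age2": BETA_AGE2,
        "var_practice": VAR_PRACTICE,
        "var_farm_int": float(COV_FARM[0, 0]),
        "cov_farm_int_slope": float(COV_FARM[0, 1]),
        "var_farm_slope": float(COV_FARM[1, 1]),
        "var_residual": VAR_RESIDUAL,
    }
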