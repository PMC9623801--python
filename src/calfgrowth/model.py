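"""Three-level random-slope growth model fitted by Gibbs sampling.

The model for weight ``y`` of a calf at age ``t`` (days) on farm ``j``
under veterinary practice ``k`` is

    y = x(t)' beta + v_k + u0_j + u1_j * t + e,

    v_k ~ N(0, sigma_v^2),  (u0, u1)_j ~ N2(0, Omega_u),
    e ~ N(0, sigma_e^2),

with ``x(t) = (1, t, t^2)`` by default (``degree=2``).  Ages enter in
raw days, so the intercept is interpretable as mean birth weight.

Priors follow the conventional noninformative choices for this model
class: flat on the fixed effects, Gamma(0.001, 0.001) on the practice
and residual precisions, and a Wishart on the farm-level precision
matrix with 2 degrees of freedom and scale ``(2 * S_u)^-1``, where
``S_u`` is a frequentist covariance estimate from the initialiser -- so
the prior precision has expectation ``S_u^-1``.

All conditional updates are exact conjugate draws; one seeded generator
drives the whole run in a fixed order, so chains are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

_VARIANCE_FLOOR = 1e-6
_GROWTH_HORIZON_DAYS = 138  # horizon of the stored cluster-rate quantiles

PARAM_COLUMNS = [
    "alpha",
    "beta_age",
    "beta_age2",
    "var_practice",
    "var_farm_int",
    "cov_farm_int_slope",
    "var_farm_slope",
    "var_residual",
]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrixBundle:
    """Response, fixed design and cluster index maps for one dataset.

    Per-farm cross-products of the random design ``z = (1, age)`` are
    precomputed once; the Gibbs sweep only recomputes the per-sweep
    residual projections.
    """

    y: np.ndarray  # (n,) response, kg
    age: np.ndarray  # (n,) age in days (float)
    X: np.ndarray  # (n, p) fixed design, columns 1, age, age^2, ...
    rec_farm: np.ndarray  # (n,) farm index per record
    rec_practice: np.ndarray  # (n,) practice index per record
    farm_practice: np.ndarray  # (J,) practice index per farm
    n_farms: int
    n_practices: int
    degree: int
    # precomputed aggregates
    XtX: np.ndarray = field(init=False)
    XtX_inv: np.ndarray = field(init=False)
    chol_XtX_inv: np.ndarray = field(init=False)
    farm_n: np.ndarray = field(init=False)  # (J,)
    farm_sum_age: np.ndarray = field(init=False)
    farm_sum_age2: np.ndarray = field(init=False)
    practice_n: np.ndarray = field(init=False)  # (K,)

    def __post_init__(self) -> None:
        self.XtX = self.X.T @ self.X
        cond = np.linalg.cond(self.XtX)
        if np.isfinite(cond) and cond < 1e14:
            self.XtX_inv = np.linalg.inv(self.XtX)
            self.chol_XtX_inv = np.linalg.cholesky(self.XtX_inv)
        else:
            # defer: a design can be inspected even when unfittable
            self.XtX_inv = None
            self.chol_XtX_inv = None
        J, K = self.n_farms, self.n_practices
        self.farm_n = np.bincount(self.rec_farm, minlength=J).astype(float)
        self.farm_sum_age = np.bincount(
            self.rec_farm, weights=self.age, minlength=J
        )
        self.farm_sum_age2 = np.bincount(
            self.rec_farm, weights=self.age**2, minlength=J
        )
        self.practice_n = np.bincount(
            self.rec_practice, minlength=K
        ).astype(float)

    @property
    def n_records(self) -> int:
        return int(self.y.size)

    def assert_fittable(self) -> None:
        """Raise if the fixed design is singular (e.g. no age spread)."""
        if self.XtX_inv is None:
            cols = ["1"] + [
                f"age^{d}" if d > 1 else "age"
                for d in range(1, self.degree + 1)
            ]
            raise ValueError(
                "fixed design is singular or near-singular; columns "
                f"{cols} are collinear -- the data lack age spread"
            )


def build_design(records: pd.DataFrame, degree: int = 2) -> DesignMatrixBundle:
    """Construct the design bundle from a selected record table.

    Raises on an empty table, on a calf appearing under two farms, or
    on a farm appearing under two practices (the model assumes strict
    nesting).
    """
    if len(records) == 0:
        raise ValueError("cannot build a design from an empty record table")
    if degree < 0:
        raise ValueError("degree must be >= 0")

    calf_farms = records.groupby("calf_id")["farm_id"].nunique()
    if (calf_farms > 1).any():
        bad = calf_farms.index[calf_farms > 1].tolist()[:5]
        raise ValueError(
            f"calves appear under more than one farm (e.g. {bad}); "
            "the model requires strict nesting"
        )
    farm_pracs = records.groupby("farm_id")["practice_id"].nunique()
    if (farm_pracs > 1).any():
        bad = farm_pracs.index[farm_pracs > 1].tolist()[:5]
        raise ValueError(
            f"farms appear under more than one practice (e.g. {bad}); "
            "the model requires strict nesting"
        )

    farm_codes, farm_ids = pd.factorize(records["farm_id"], sort=True)
    practice_codes, practice_ids = pd.factorize(
        records["practice_id"], sort=True
    )
    J, K = len(farm_ids), len(practice_ids)
    farm_practice = np.zeros(J, dtype=int)
    farm_practice[farm_codes] = practice_codes

    age = records["age_days"].to_numpy(dtype=float)
    X = np.vander(age, degree + 1, increasing=True)
    return DesignMatrixBundle(
        y=records["weight_kg"].to_numpy(dtype=float),
        age=age,
        X=X,
        rec_farm=farm_codes.astype(int),
        rec_practice=practice_codes.astype(int),
        farm_practice=farm_practice,
        n_farms=J,
        n_practices=K,
        degree=degree,
    )


# ---------------------------------------------------------------------------
# priors, state, settings
# ---------------------------------------------------------------------------


@dataclass
class PriorSpec:
    """Conjugate priors for the variance components.

    Scalar precisions ``1/sigma_v^2`` and ``1/sigma_e^2`` get
    Gamma(shape, rate) priors; the farm-level precision matrix gets a
    Wishart(df, scale) prior.  ``default_from_estimate`` builds the
    standard noninformative choice: Gamma(0.001, 0.001) and
    Wishart(2, (2 * S_u)^-1) with ``S_u`` the initialiser's farm
    covariance estimate, so E[precision] = S_u^-1.
    """

    gamma_shape_practice: float = 0.001
    gamma_rate_practice: float = 0.001
    gamma_shape_residual: float = 0.001
    gamma_rate_residual: float = 0.001
    wishart_df: float = 2.0
    wishart_scale: np.ndarray = field(
        default_factory=lambda: np.eye(2) * 0.5
    )

    def validate(self) -> None:
        if min(
            self.gamma_shape_practice,
            self.gamma_rate_practice,
            self.gamma_shape_residual,
            self.gamma_rate_residual,
        ) <= 0:
            raise ValueError("Gamma shapes and rates must be positive")
        if self.wishart_df < 2:
            raise ValueError("wishart_df must be >= 2 for a 2x2 precision")
        scale = np.asarray(self.wishart_scale, dtype=float)
        if scale.shape != (2, 2) or not np.allclose(scale, scale.T):
            raise ValueError("wishart_scale must be symmetric 2x2")
        if np.linalg.eigvalsh(scale).min() <= 0:
            raise ValueError("wishart_scale must be positive definite")

    @classmethod
    def default_from_estimate(cls, s_u: np.ndarray) -> "PriorSpec":
        s_u = np.asarray(s_u, dtype=float)
        spec = cls(wishart_df=2.0, wishart_scale=np.linalg.inv(2.0 * s_u))
        spec.validate()
        return spec


@dataclass
class ParameterState:
    """One full realisation of the model unknowns."""

    beta: np.ndarray  # (p,) fixed effects
    v: np.ndarray  # (K,) practice intercepts
    u: np.ndarray  # (J, 2) farm (intercept, slope)
    var_practice: float
    cov_farm: np.ndarray  # (2, 2)
    var_residual: float

    @property
    def alpha(self) -> float:
        return float(self.beta[0])

    def copy(self) -> "ParameterState":
        return ParameterState(
            beta=self.beta.copy(),
            v=self.v.copy(),
            u=self.u.copy(),
            var_practice=self.var_practice,
            cov_farm=self.cov_farm.copy(),
            var_residual=self.var_residual,
        )

    def validate(self) -> None:
        if self.var_practice <= 0 or self.var_residual <= 0:
            raise ValueError("scalar variances must be positive")
        if np.linalg.eigvalsh(self.cov_farm).min() <= 0:
            raise ValueError("cov_farm must be positive definite")


@dataclass
class McmcSettings:
    """Sampling schedule.  ``total_iterations`` counts post-burn-in sweeps."""

    burn_in: int = 100_000
    total_iterations: int = 1_000_000
    thin: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.total_iterations % self.thin:
            raise ValueError("total_iterations must be divisible by thin")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    @property
    def n_stored(self) -> int:
        return self.total_iterations // self.thin

    @classmethod
    def production(cls, seed: int = 0) -> "McmcSettings":
        """The full schedule of the original analysis."""
        return cls(burn_in=100_000, total_iterations=1_000_000, thin=100, seed=seed)

    @classmethod
    def desk(cls, seed: int = 0) -> "McmcSettings":
        """Reduced schedule: completes in minutes on one CPU."""
        return cls(burn_in=5_000, total_iterations=50_000, thin=10, seed=seed)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def initialize(
    design: DesignMatrixBundle,
) -> tuple[ParameterState, np.ndarray]:
    """Starting values from OLS plus moment estimators.

    Fixed effects come from ordinary least squares on the fixed design.
    Variance components come from analysis-of-variance style moment
    estimators: each farm's residuals are regressed on (1, age) -- the
    farm intercept estimate absorbs both the practice effect and the
    farm intercept effect -- then practice effects are the per-practice
    means of those farm intercepts.  Sampling noise of the cluster
    estimates is subtracted out and the results are floored at a small
    positive value.  Returns ``(state, S_u_hat)`` where ``S_u_hat`` is
    the farm-level 2x2 covariance estimate used to build the Wishart
    prior scale.
    """
    design.assert_fittable()
    y, X, age = design.y, design.X, design.age
    n, J, K = design.n_records, design.n_farms, design.n_practices

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta

    # per-farm (intercept, slope) regressions on the raw residual:
    # intercept estimate c0_j ~ v_k + u0_j + noise, slope c1_j ~ u1_j
    t0 = np.bincount(design.rec_farm, weights=resid, minlength=J)
    t1 = np.bincount(design.rec_farm, weights=resid * age, minlength=J)
    a = design.farm_n
    b = design.farm_sum_age
    c = design.farm_sum_age2
    det = a * c - b * b
    ok = det > 1e-8
    c0 = np.zeros(J)
    c1 = np.zeros(J)
    c0[ok] = (c[ok] * t0[ok] - b[ok] * t1[ok]) / det[ok]
    c1[ok] = (a[ok] * t1[ok] - b[ok] * t0[ok]) / det[ok]
    c0[~ok] = np.divide(
        t0[~ok], a[~ok], out=np.zeros(int((~ok).sum())), where=a[~ok] > 0
    )

    # practice effects as means of farm intercept estimates
    farms_per_practice = np.maximum(
        np.bincount(design.farm_practice, minlength=K), 1
    )
    v_hat = (
        np.bincount(design.farm_practice, weights=c0, minlength=K)
        / farms_per_practice
    )
    u_hat = np.column_stack((c0 - v_hat[design.farm_practice], c1))

    # residual variance from within-farm leftovers
    fitted = c0[design.rec_farm] + c1[design.rec_farm] * age
    within = resid - fitted
    dof = max(n - 2 * J - X.shape[1], 1)
    var_e = max(float(within @ within) / dof, _VARIANCE_FLOOR)

    # farm covariance, debiased for (a) the sampling covariance of the
    # per-farm estimates, Cov((c0, c1)_j | u_j) ~= var_e * (Z_j'Z_j)^-1,
    # and (b) the within-practice centering of the intercepts, which
    # scales both signal and noise in u_hat[:, 0] by (1 - 1/m) for m
    # farms per practice
    if J > 1:
        center = max(1.0 - 1.0 / float(farms_per_practice.mean()), 0.5)
        s_raw = np.cov(np.column_stack((c0, c1)), rowvar=False)
        s_raw[0, 0] = float(np.var(u_hat[:, 0], ddof=1)) / center
        s_raw[0, 1] = s_raw[1, 0] = (
            float(np.cov(u_hat[:, 0], u_hat[:, 1])[0, 1]) / center
        )
        noise = np.zeros((2, 2))
        if ok.any():
            inv00 = c[ok] / det[ok]
            inv01 = -b[ok] / det[ok]
            inv11 = a[ok] / det[ok]
            noise = var_e * np.array(
                [
                    [inv00.mean(), inv01.mean()],
                    [inv01.mean(), inv11.mean()],
                ]
            )
        s_u = s_raw - noise
    else:
        s_u = np.eye(2)
    s_u = _floor_spd(s_u)

    # practice variance from the spread of practice means, debiased for
    # the farm-level and residual noise carried into each mean
    if K > 1:
        var_v = float(np.var(v_hat, ddof=1))
        mean_noise = float(s_u[0, 0]) + (
            var_e * float((c[ok] / det[ok]).mean()) if ok.any() else 0.0
        )
        var_v -= mean_noise / float(farms_per_practice.mean())
    else:
        var_v = _VARIANCE_FLOOR
    var_v = max(var_v, _VARIANCE_FLOOR)

    state = ParameterState(
        beta=beta,
        v=v_hat,
        u=u_hat,
        var_practice=var_v,
        cov_farm=s_u.copy(),
        var_residual=var_e,
    )
    return state, s_u


def _floor_spd(mat: np.ndarray, floor: float = _VARIANCE_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to the SPD cone with floored eigenvalues."""
    mat = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(mat)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


# ---------------------------------------------------------------------------
# Gibbs sweep
# ---------------------------------------------------------------------------


def _inv2x2(m: np.ndarray) -> np.ndarray:
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


def _wishart_2x2(
    rng: np.random.Generator, df: float, scale: np.ndarray
) -> np.ndarray:
    """Bartlett draw of a 2x2 Wishart(df, scale) matrix."""
    L = np.linalg.cholesky(scale)
    A = np.zeros((2, 2))
    A[0, 0] = np.sqrt(rng.chisquare(df))
    A[1, 1] = np.sqrt(rng.chisquare(df - 1.0))
    A[1, 0] = rng.standard_normal()
    LA = L @ A
    return LA @ LA.T


def gibbs_step(
    state: ParameterState,
    design: DesignMatrixBundle,
    priors: PriorSpec,
    rng: np.random.Generator,
    *,
    include_practice: bool = True,
    include_farm: bool = True,
    fixed_residual_variance: float | None = None,
) -> ParameterState:
    """One full sweep of exact conditional draws.

    Update order (fixed; all draws consumed from ``rng`` in this
    order): fixed effects, practice effects, farm effect pairs,
    practice precision, residual precision, farm precision matrix.
    Levels can be switched off for reduced sub-models; a fixed residual
    variance skips its update (used by conjugate-oracle checks).
    """
    s = state.copy()
    y, X, age = design.y, design.X, design.age
    n, J, K = design.n_records, design.n_farms, design.n_practices
    rf, rp = design.rec_farm, design.rec_practice

    def random_part() -> np.ndarray:
        part = np.zeros(n)
        if include_practice:
            part += s.v[rp]
        if include_farm:
            part += s.u[rf, 0] + s.u[rf, 1] * age
        return part

    # (1) fixed effects: flat prior => N((X'X)^-1 X'r, sigma_e^2 (X'X)^-1)
    r = y - random_part()
    mean = design.XtX_inv @ (X.T @ r)
    z = rng.standard_normal(X.shape[1])
    s.beta = mean + np.sqrt(s.var_residual) * (design.chol_XtX_inv @ z)

    xb = X @ s.beta
    tau_e = 1.0 / s.var_residual

    # (2) practice intercepts: shrunken practice residual means
    if include_practice:
        r = y - xb
        if include_farm:
            r = r - s.u[rf, 0] - s.u[rf, 1] * age
        sums = np.bincount(rp, weights=r, minlength=K)
        prec = design.practice_n * tau_e + 1.0 / s.var_practice
        mu = tau_e * sums / prec
        s.v = mu + rng.standard_normal(K) / np.sqrt(prec)

    # (3) farm (intercept, slope) pairs: conditional bivariate normals
    if include_farm:
        r = y - xb
        if include_practice:
            r = r - s.v[rp]
        t0 = np.bincount(rf, weights=r, minlength=J) * tau_e
        t1 = np.bincount(rf, weights=r * age, minlength=J) * tau_e
        om_inv = _inv2x2(s.cov_farm)
        A = design.farm_n * tau_e + om_inv[0, 0]
        B = design.farm_sum_age * tau_e + om_inv[0, 1]
        C = design.farm_sum_age2 * tau_e + om_inv[1, 1]
        det = A * C - B * B
        c00, c01, c11 = C / det, -B / det, A / det
        m0 = c00 * t0 + c01 * t1
        m1 = c01 * t0 + c11 * t1
        l11_sq = c00
        l22_sq = c11 - c01 * c01 / c00
        if np.any(l11_sq <= 0) or np.any(l22_sq <= 0):
            # numerically non-PD conditional covariance: jitter once
            c00 = c00 + 1e-10
            c11 = c11 + 1e-10
            l11_sq = c00
            l22_sq = c11 - c01 * c01 / c00
            if np.any(l11_sq <= 0) or np.any(l22_sq <= 0):
                bad = int(np.flatnonzero((l11_sq <= 0) | (l22_sq <= 0))[0])
                raise FloatingPointError(
                    f"conditional covariance for farm {bad} is not positive "
                    "definite after jitter"
                )
        l11 = np.sqrt(l11_sq)
        l21 = c01 / l11
        l22 = np.sqrt(l22_sq)
        z0 = rng.standard_normal(J)
        z1 = rng.standard_normal(J)
        s.u = np.column_stack((m0 + l11 * z0, m1 + l21 * z0 + l22 * z1))

    # (4) practice precision
    if include_practice:
        shape = priors.gamma_shape_practice + K / 2.0
        rate = priors.gamma_rate_practice + float(s.v @ s.v) / 2.0
        s.var_practice = 1.0 / rng.gamma(shape, 1.0 / rate)

    # (5) residual precision
    resid = y - xb - random_part()
    if fixed_residual_variance is None:
        shape = priors.gamma_shape_residual + n / 2.0
        rate = priors.gamma_rate_residual + float(resid @ resid) / 2.0
        s.var_residual = 1.0 / rng.gamma(shape, 1.0 / rate)
    else:
        s.var_residual = fixed_residual_variance

    # (6) farm precision matrix: Wishart with df = df0 + J and
    #     scale = (scale0^-1 + sum_j u_j u_j')^-1; with J = 0 this is
    #     exactly the prior.
    if include_farm:
        scale_inv = np.linalg.inv(priors.wishart_scale) + s.u.T @ s.u
        post_scale = np.linalg.inv(scale_inv)
        prec = _wishart_2x2(rng, priors.wishart_df + J, post_scale)
        s.cov_farm = _inv2x2(prec)

    return s


# ---------------------------------------------------------------------------
# chain container and runner
# ---------------------------------------------------------------------------


@dataclass
class PosteriorChain:
    """Thinned post-burn-in draws plus sampler metadata.

    ``params`` has one row per stored draw; columns follow
    ``PARAM_COLUMNS`` (reduced sub-models omit the columns of levels
    they exclude).  ``deviance`` is the conditional deviance
    ``-2 log N(y | fitted, sigma_e^2)`` per stored draw.  Random-effect
    vectors are summarised (posterior means, per-draw cluster-mean
    quantiles) unless ``store_random_effects`` was requested at run
    time.
    """

    params: pd.DataFrame
    deviance: np.ndarray
    settings: McmcSettings
    priors: PriorSpec
    n_records: int
    n_farms: int
    n_practices: int
    degree: int
    posterior_mean_v: np.ndarray | None = None
    posterior_mean_u: np.ndarray | None = None
    cluster_quantiles: pd.DataFrame | None = None
    v_draws: np.ndarray | None = None  # (D, K) if stored
    u_draws: np.ndarray | None = None  # (D, J, 2) if stored
    farm_practice: np.ndarray | None = None  # (J,)

    @property
    def n_draws(self) -> int:
        return len(self.params)

    def posterior_means(self) -> dict[str, float]:
        return self.params.mean().to_dict()

    def save(self, directory: str | Path, stem: str = "chain") -> None:
        """Write the stored draws as CSV plus a JSON metadata document."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = self.params.copy()
        out["deviance"] = self.deviance
        out.to_csv(directory / f"{stem}.csv", index=False)
        meta = {
            "burn_in": self.settings.burn_in,
            "total_iterations": self.settings.total_iterations,
            "thin": self.settings.thin,
            "seed": self.settings.seed,
            "n_records": self.n_records,
            "n_farms": self.n_farms,
            "n_practices": self.n_practices,
            "degree": self.degree,
            "priors": {
                "gamma_shape_practice": self.priors.gamma_shape_practice,
                "gamma_rate_practice": self.priors.gamma_rate_practice,
                "gamma_shape_residual": self.priors.gamma_shape_residual,
                "gamma_rate_residual": self.priors.gamma_rate_residual,
                "wishart_df": self.priors.wishart_df,
                "wishart_scale": np.asarray(self.priors.wishart_scale).tolist(),
            },
            "posterior_mean_v": (
                self.posterior_mean_v.tolist()
                if self.posterior_mean_v is not None
                else None
            ),
            "posterior_mean_u": (
                self.posterior_mean_u.tolist()
                if self.posterior_mean_u is not None
                else None
            ),
            "farm_practice": (
                self.farm_practice.tolist()
                if self.farm_practice is not None
                else None
            ),
        }
        (directory / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))
        if self.cluster_quantiles is not None:
            self.cluster_quantiles.to_csv(
                directory / f"{stem}_cluster_quantiles.csv", index=False
            )

    @classmethod
    def load(cls, directory: str | Path, stem: str = "chain") -> "PosteriorChain":
        directory = Path(directory)
        table = pd.read_csv(directory / f"{stem}.csv")
        meta = json.loads((directory / f"{stem}_meta.json").read_text())
        priors = PriorSpec(
            gamma_shape_practice=meta["priors"]["gamma_shape_practice"],
            gamma_rate_practice=meta["priors"]["gamma_rate_practice"],
            gamma_shape_residual=meta["priors"]["gamma_shape_residual"],
            gamma_rate_residual=meta["priors"]["gamma_rate_residual"],
            wishart_df=meta["priors"]["wishart_df"],
            wishart_scale=np.asarray(meta["priors"]["wishart_scale"]),
        )
        settings = McmcSettings(
            burn_in=meta["burn_in"],
            total_iterations=meta["total_iterations"],
            thin=meta["thin"],
            seed=meta["seed"],
        )
        deviance = table.pop("deviance").to_numpy()
        qpath = directory / f"{stem}_cluster_quantiles.csv"
        quantiles = pd.read_csv(qpath) if qpath.exists() else None

        def _arr(key):
            val = meta.get(key)
            return np.asarray(val) if val is not None else None

        return cls(
            params=table,
            deviance=deviance,
            settings=settings,
            priors=priors,
            n_records=meta["n_records"],
            n_farms=meta["n_farms"],
            n_practices=meta["n_practices"],
            degree=meta["degree"],
            cluster_quantiles=quantiles,
            posterior_mean_v=_arr("posterior_mean_v"),
            posterior_mean_u=_arr("posterior_mean_u"),
            farm_practice=_arr("farm_practice"),
        )


def run_mcmc(
    design: DesignMatrixBundle,
    priors: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    *,
    init: ParameterState | None = None,
    include_practice: bool = True,
    include_farm: bool = True,
    fixed_residual_variance: float | None = None,
    store_random_effects: bool = False,
) -> PosteriorChain:
    """Run the Gibbs sampler and collect a thinned posterior chain.

    When ``priors`` is ``None`` the initialiser's farm covariance
    estimate seeds the default Wishart scale.  Burn-in sweeps are
    discarded; every ``thin``-th post-burn-in state is stored.  The run
    is deterministic given ``settings.seed``.
    """
    settings = settings or McmcSettings.desk()
    settings.validate()
    design.assert_fittable()
    if init is None or priors is None:
        state0, s_u_hat = initialize(design)
        if init is None:
            init = state0
        if priors is None:
            priors = PriorSpec.default_from_estimate(s_u_hat)
    priors.validate()
    if fixed_residual_variance is not None:
        init = replace(init, var_residual=fixed_residual_variance)

    rng = np.random.default_rng(settings.seed)
    n_stored = settings.n_stored
    J, K, n = design.n_farms, design.n_practices, design.n_records
    h = float(_GROWTH_HORIZON_DAYS)

    columns = ["alpha"]
    if design.degree >= 1:
        columns.append("beta_age")
    if design.degree >= 2:
        columns.append("beta_age2")
    if include_practice:
        columns.append("var_practice")
    if include_farm:
        columns += ["var_farm_int", "cov_farm_int_slope", "var_farm_slope"]
    columns.append("var_residual")

    draws = np.zeros((n_stored, len(columns)))
    deviance = np.zeros(n_stored)
    sum_v = np.zeros(K)
    sum_u = np.zeros((J, 2))
    cq = np.full((n_stored, 4), np.nan)
    v_draws = np.zeros((n_stored, K)) if store_random_effects else None
    u_draws = np.zeros((n_stored, J, 2)) if store_random_effects else None

    state = init
    step_kwargs = dict(
        include_practice=include_practice,
        include_farm=include_farm,
        fixed_residual_variance=fixed_residual_variance,
    )
    try:
        for it in range(settings.burn_in):
            state = gibbs_step(state, design, priors, rng, **step_kwargs)
        stored = 0
        for it in range(settings.total_iterations):
            state = gibbs_step(state, design, priors, rng, **step_kwargs)
            if (it + 1) % settings.thin:
                continue
            row = [state.beta[0]]
            if design.degree >= 1:
                row.append(state.beta[1])
            if design.degree >= 2:
                row.append(state.beta[2])
            if include_practice:
                row.append(state.var_practice)
            if include_farm:
                row += [
                    state.cov_farm[0, 0],
                    state.cov_farm[0, 1],
                    state.cov_farm[1, 1],
                ]
            row.append(state.var_residual)
            draws[stored] = row

            fitted = design.X @ state.beta
            if include_practice:
                fitted = fitted + state.v[design.rec_practice]
            if include_farm:
                fitted = (
                    fitted
                    + state.u[design.rec_farm, 0]
                    + state.u[design.rec_farm, 1] * design.age
                )
            sse = float(np.sum((design.y - fitted) ** 2))
            deviance[stored] = (
                n * np.log(2.0 * np.pi * state.var_residual)
                + sse / state.var_residual
            )

            if include_practice:
                sum_v += state.v
            if include_farm:
                sum_u += state.u
            if include_farm and J >= 2:
                vpart = (
                    state.v[design.farm_practice] if include_practice else 0.0
                )
                bw = state.beta[0] + vpart + state.u[:, 0]
                rate = state.u[:, 1].copy()
                if design.degree >= 1:
                    rate += state.beta[1]
                if design.degree >= 2:
                    rate += state.beta[2] * h
                cq[stored, 0:2] = np.quantile(bw, [0.025, 0.975])
                cq[stored, 2:4] = np.quantile(rate, [0.025, 0.975])
            if store_random_effects:
                v_draws[stored] = state.v
                u_draws[stored] = state.u
            stored += 1
    except FloatingPointError as err:
        raise RuntimeError(f"Gibbs sweep failed at iteration {it}: {err}") from err

    params = pd.DataFrame(draws, columns=columns)
    quantiles = pd.DataFrame(
        cq,
        columns=[
            "birth_weight_q025",
            "birth_weight_q975",
            "cum_rate_q025",
            "cum_rate_q975",
        ],
    )
    return PosteriorChain(
        params=params,
        deviance=deviance,
        settings=settings,
        priors=priors,
        n_records=n,
        n_farms=J,
        n_practices=K,
        degree=design.degree,
        posterior_mean_v=sum_v / n_stored if include_practice else None,
        posterior_mean_u=sum_u / n_stored if include_farm else None,
        cluster_quantiles=quantiles if include_farm and J >= 2 else None,
        v_draws=v_draws,
        u_draws=u_draws,
        farm_practice=design.farm_practice.copy(),
    )
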