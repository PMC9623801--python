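"""Synthetic calf-weight populations with known ground truth.

The generator emulates the structure of a national calf weight-recording
service: veterinary practices service farms, farms rear calves, and
calves are weighed on irregular, farm-specific schedules.  Weights
follow the three-level random-slope growth model

    y = alpha + beta1*age + beta2*age^2 + v_practice + u0_farm
        + u1_farm*age + e,

so every downstream stage (selection, model fitting, derived
quantities) can be tested against known generating values.

Defaults reproduce the conditions of the source dataset: 28 practices,
~139 farms, ~19,700 calves, a median of 3 weight measurements per calf
(IQR 2-3), follow-up ages 1-138 days with attrition at older ages, and
75% of calves carrying a confirmed birth weight.  The per-calf total
measurement count is 1 + NegativeBinomial, calibrated once so the total
has quartiles (2, 3, 3).

Corruption emulates the data-entry defects the selection cascade
removes: implausible ages, weights outside (30, 225] kg, weights flagged
as estimates, and farms with a short apparent recording window.
Corrupted rows are tracked per record in the returned ground truth, and
the corruption classes are applied to disjoint record sets so each
selection stage can be checked against an exact injected count.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from calfgrowth import reference
from calfgrowth.records import RECORD_COLUMNS, validate_records

_STUDY_START = np.datetime64("2014-06-05")
_STUDY_DAYS = 2095  # service window emulated by the farm calendars


@dataclass
class CorruptionConfig:
    """Rates of the data defects the selection cascade removes.

    All rates are probabilities in [0, 1].  ``age_implausible``,
    ``estimate_flag`` and ``weight_out_of_range`` apply per follow-up
    record; ``short_window_farm`` applies per farm (the whole farm's
    recording calendar is compressed to span well under a year).
    """

    age_implausible: float = 0.0
    estimate_flag: float = 0.0
    weight_out_of_range: float = 0.0
    short_window_farm: float = 0.0

    def validate(self) -> None:
        for name in (
            "age_implausible",
            "estimate_flag",
            "weight_out_of_range",
            "short_window_farm",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"corruption rate {name}={rate} outside [0, 1]")


@dataclass
class SimulationConfig:
    """Configuration of one synthetic population.

    Cluster counts may be given either as exact totals (``n_farms``,
    ``n_calves``, allocated as evenly as possible) or left ``None`` to
    draw per-practice / per-farm counts from shifted negative-binomial
    distributions with the given means and dispersions.
    """

    n_practices: int = 28
    n_farms: int | None = 139
    n_calves: int | None = 19_708
    farms_per_practice_mean: float = 5.0
    farms_per_practice_dispersion: float = 2.0
    calves_per_farm_mean: float = 142.0
    calves_per_farm_dispersion: float = 1.5
    # total measurements per calf = 1 + NB(dispersion, mean); calibrated
    # to the reported median of 3 and IQR 2-3.  measurements_fixed
    # overrides the distribution with a constant per-calf total.
    measurements_nb_mean: float = 1.7
    measurements_nb_dispersion: float = 30.0
    measurements_fixed: int | None = None
    age_range_days: tuple[int, int] = (1, 138)
    attrition_rate: float = 0.5  # linear thinning of weighings with age
    fixed_effects: tuple[float, float, float] = (
        reference.ALPHA,
        reference.BETA_AGE,
        reference.BETA_AGE2,
    )
    var_practice: float = reference.VAR_PRACTICE
    cov_farm: np.ndarray = field(
        default_factory=lambda: reference.COV_FARM.copy()
    )
    var_calf_residual: float = reference.VAR_RESIDUAL
    birth_weight_confirmed_fraction: float = 0.75
    farm_window_days: tuple[int, int] = (550, 1800)
    short_window_days: int = 150  # birth window of short-calendar farms
    corruption: CorruptionConfig = field(default_factory=CorruptionConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_practices < 1:
            raise ValueError("n_practices must be >= 1")
        if self.var_practice < 0 or self.var_calf_residual < 0:
            raise ValueError("variance components must be non-negative")
        cov = np.asarray(self.cov_farm, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError(f"cov_farm must be symmetric 2x2, got {cov!r}")
        if np.any(cov != 0.0):
            eigvals = np.linalg.eigvalsh(cov)
            if eigvals.min() <= 0:
                raise ValueError(
                    "cov_farm is not positive definite "
                    f"(eigenvalues {eigvals}): {cov!r}"
                )
        lo, hi = self.age_range_days
        if not 0 < lo <= hi:
            raise ValueError(f"invalid age_range_days {self.age_range_days}")
        if not 0.0 <= self.birth_weight_confirmed_fraction <= 1.0:
            raise ValueError("birth_weight_confirmed_fraction outside [0, 1]")
        if not 0.0 <= self.attrition_rate <= 1.0:
            raise ValueError("attrition_rate outside [0, 1]")
        self.corruption.validate()


@dataclass
class TrueParameters:
    """Realised ground truth of one simulated population.

    ``record_flags`` is aligned row-for-row with the returned record
    table and marks which records each corruption class touched, so
    tests can predict selection-stage counts exactly.
    """

    fixed_effects: tuple[float, float, float]
    var_practice: float
    cov_farm: np.ndarray
    var_calf_residual: float
    practice_effects: np.ndarray  # (K,)
    farm_effects: np.ndarray  # (J, 2) intercept, slope
    farm_practice: np.ndarray  # (J,) practice index of each farm
    calf_farm: np.ndarray  # (C,) farm index of each calf
    short_window_farms: np.ndarray  # farm indices with compressed calendars
    corruption_tallies: dict[str, int]
    record_flags: pd.DataFrame

    def save(self, path: str | Path) -> None:
        """Write the ground truth as a JSON document."""
        doc = {
            "fixed_effects": list(self.fixed_effects),
            "var_practice": self.var_practice,
            "cov_farm": np.asarray(self.cov_farm).tolist(),
            "var_calf_residual": self.var_calf_residual,
            "practice_effects": self.practice_effects.tolist(),
            "farm_effects": self.farm_effects.tolist(),
            "farm_practice": self.farm_practice.tolist(),
            "calf_farm": self.calf_farm.tolist(),
            "short_window_farms": self.short_window_farms.tolist(),
            "corruption_tallies": self.corruption_tallies,
            "record_flags": {
                c: self.record_flags[c].astype(int).tolist()
                for c in self.record_flags.columns
            },
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "TrueParameters":
        doc = json.loads(Path(path).read_text())
        return cls(
            fixed_effects=tuple(doc["fixed_effects"]),
            var_practice=doc["var_practice"],
            cov_farm=np.asarray(doc["cov_farm"]),
            var_calf_residual=doc["var_calf_residual"],
            practice_effects=np.asarray(doc["practice_effects"]),
            farm_effects=np.asarray(doc["farm_effects"]),
            farm_practice=np.asarray(doc["farm_practice"], dtype=int),
            calf_farm=np.asarray(doc["calf_farm"], dtype=int),
            short_window_farms=np.asarray(doc["short_window_farms"], dtype=int),
            corruption_tallies=dict(doc["corruption_tallies"]),
            record_flags=pd.DataFrame(
                {c: np.asarray(v, dtype=bool) for c, v in doc["record_flags"].items()}
            ),
        )


def _shifted_nb_counts(
    rng: np.random.Generator, n: int, mean: float, dispersion: float
) -> np.ndarray:
    """Counts >= 1 distributed as 1 + NB(dispersion, mean - 1)."""
    extra_mean = max(mean - 1.0, 0.0)
    if extra_mean == 0.0:
        return np.ones(n, dtype=int)
    p = dispersion / (dispersion + extra_mean)
    return 1 + rng.negative_binomial(dispersion, p, size=n)


def _allocate(total: int, n_groups: int) -> np.ndarray:
    """Split ``total`` items over ``n_groups`` as evenly as possible."""
    base, rem = divmod(total, n_groups)
    counts = np.full(n_groups, base, dtype=int)
    counts[:rem] += 1
    return counts


def _draw_farm_effects(
    rng: np.random.Generator, cov: np.ndarray, n: int
) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if not np.any(cov != 0.0):
        return np.zeros((n, 2))
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"cov_farm is not positive definite: {cov!r}"
        ) from err
    return rng.standard_normal((n, 2)) @ chol.T


def _follow_up_ages(
    rng: np.random.Generator,
    n: int,
    age_lo: int,
    age_hi: int,
    attrition_rate: float,
) -> np.ndarray:
    """Follow-up ages, uniform with linear thinning towards older ages.

    Thinning is by rejection: a proposed age ``a`` is kept with
    probability ``1 - rate * (a - lo) / (hi - lo)``, emulating the
    decreasing number of weighings as calves age without changing the
    per-calf weighing count.
    """
    if n == 0:
        return np.zeros(0, dtype=int)
    ages = np.zeros(n, dtype=int)
    pending = np.arange(n)
    span = max(age_hi - age_lo, 1)
    while pending.size:
        proposal = rng.integers(age_lo, age_hi + 1, size=pending.size)
        keep_p = 1.0 - attrition_rate * (proposal - age_lo) / span
        accepted = rng.random(pending.size) < keep_p
        ages[pending[accepted]] = proposal[accepted]
        pending = pending[~accepted]
    return ages


def simulate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TrueParameters]:
    """Generate one synthetic weight-recording table plus ground truth.

    Returns ``(records, truth)``.  The record table follows the schema
    in :mod:`calfgrowth.records`; confirmed birth weights appear as rows
    with ``age_days == 0`` and ``is_birth_weight`` set, ready to be
    split out by the selection pipeline.  Identical configs (including
    seed) reproduce byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    alpha, beta1, beta2 = config.fixed_effects
    age_lo, age_hi = config.age_range_days

    # --- hierarchy -----------------------------------------------------
    n_k = config.n_practices
    if config.n_farms is not None:
        farms_per_practice = _allocate(config.n_farms, n_k)
    else:
        farms_per_practice = _shifted_nb_counts(
            rng, n_k, config.farms_per_practice_mean,
            config.farms_per_practice_dispersion,
        )
    n_j = int(farms_per_practice.sum())
    farm_practice = np.repeat(np.arange(n_k), farms_per_practice)

    if config.n_calves is not None:
        calves_per_farm = _allocate(config.n_calves, n_j)
    else:
        calves_per_farm = _shifted_nb_counts(
            rng, n_j, config.calves_per_farm_mean,
            config.calves_per_farm_dispersion,
        )
    n_c = int(calves_per_farm.sum())
    calf_farm = np.repeat(np.arange(n_j), calves_per_farm)

    # --- random effects ------------------------------------------------
    v = rng.normal(0.0, np.sqrt(config.var_practice), size=n_k)
    u = _draw_farm_effects(rng, config.cov_farm, n_j)

    # --- farm calendars ------------------------------------------------
    short_mask = rng.random(n_j) < config.corruption.short_window_farm
    window = rng.integers(
        config.farm_window_days[0], config.farm_window_days[1] + 1, size=n_j
    )
    window[short_mask] = config.short_window_days
    farm_start = rng.integers(0, max(_STUDY_DAYS - window.max(), 1), size=n_j)

    # --- per-calf schedules --------------------------------------------
    if config.measurements_fixed is not None:
        totals = np.full(n_c, config.measurements_fixed, dtype=int)
    else:
        totals = _shifted_nb_counts(
            rng, n_c, 1.0 + config.measurements_nb_mean,
            config.measurements_nb_dispersion,
        )
    n_follow = totals - 1
    confirmed = rng.random(n_c) < config.birth_weight_confirmed_fraction
    birth_offset = rng.integers(0, np.maximum(window[calf_farm] - age_hi, 1))
    birth_day = farm_start[calf_farm] + birth_offset

    n_rows = int(n_follow.sum() + confirmed.sum())
    rec_calf = np.concatenate(
        [np.repeat(np.arange(n_c), n_follow), np.flatnonzero(confirmed)]
    )
    ages = np.concatenate(
        [
            _follow_up_ages(
                rng, int(n_follow.sum()), age_lo, age_hi, config.attrition_rate
            ),
            np.zeros(int(confirmed.sum()), dtype=int),
        ]
    )
    is_birth = np.zeros(n_rows, dtype=bool)
    is_birth[int(n_follow.sum()):] = True

    # stable order: calf, then age, birth rows first within calf
    order = np.lexsort((~is_birth, ages, rec_calf))
    rec_calf, ages, is_birth = rec_calf[order], ages[order], is_birth[order]

    rec_farm = calf_farm[rec_calf]
    rec_practice = farm_practice[rec_farm]
    mean_curve = alpha + beta1 * ages + beta2 * ages.astype(float) ** 2
    noise = rng.normal(0.0, np.sqrt(config.var_calf_residual), size=n_rows)
    weight = (
        mean_curve
        + v[rec_practice]
        + u[rec_farm, 0]
        + u[rec_farm, 1] * ages
        + noise
    )

    is_estimate = np.zeros(n_rows, dtype=bool)
    flags = pd.DataFrame(
        {
            "age_corrupted": np.zeros(n_rows, dtype=bool),
            "estimate_flagged": np.zeros(n_rows, dtype=bool),
            "weight_corrupted": np.zeros(n_rows, dtype=bool),
            "on_short_farm": short_mask[rec_farm],
        }
    )

    # --- corruption (disjoint classes, follow-up rows only) ------------
    eligible = ~is_birth & ~flags["on_short_farm"].to_numpy()
    corr = config.corruption

    def _sample(mask: np.ndarray, rate: float) -> np.ndarray:
        hit = np.flatnonzero(mask)
        return hit[rng.random(hit.size) < rate]

    idx_age = _sample(eligible, corr.age_implausible)
    eligible[idx_age] = False
    bad_ages = rng.integers(age_hi + 1, 2000, size=idx_age.size)
    ages[idx_age] = bad_ages
    flags.loc[idx_age, "age_corrupted"] = True

    idx_est = _sample(eligible, corr.estimate_flag)
    eligible[idx_est] = False
    is_estimate[idx_est] = True
    flags.loc[idx_est, "estimate_flagged"] = True

    idx_wt = _sample(eligible, corr.weight_out_of_range)
    eligible[idx_wt] = False
    low = rng.random(idx_wt.size) < 0.5
    bad_w = np.where(
        low,
        rng.uniform(5.0, reference.WEIGHT_LOWER_EXCLUSIVE, size=idx_wt.size),
        rng.uniform(
            reference.WEIGHT_UPPER_INCLUSIVE + 0.1, 400.0, size=idx_wt.size
        ),
    )
    weight[idx_wt] = bad_w
    flags.loc[idx_wt, "weight_corrupted"] = True

    # --- assemble ------------------------------------------------------
    birth_date = _STUDY_START + birth_day[rec_calf].astype("timedelta64[D]")
    recording_date = birth_date + ages.astype("timedelta64[D]")
    records = pd.DataFrame(
        {
            "practice_id": rec_practice,
            "farm_id": rec_farm,
            "calf_id": rec_calf,
            "birth_date": pd.to_datetime(birth_date),
            "recording_date": pd.to_datetime(recording_date),
            "age_days": ages,
            "weight_kg": np.maximum(weight, 0.1),  # weights are positive
            "is_estimate": is_estimate,
            "is_birth_weight": is_birth,
        },
        columns=RECORD_COLUMNS,
    )
    validate_records(records)

    tallies = {
        "age_implausible": int(idx_age.size),
        "estimate_flagged": int(idx_est.size),
        "weight_out_of_range": int(idx_wt.size),
        "short_window_farms": int(short_mask.sum()),
        "short_window_records": int(flags["on_short_farm"].sum()),
        "confirmed_birth_weights": int(confirmed.sum()),
    }
    truth = TrueParameters(
        fixed_effects=(alpha, beta1, beta2),
        var_practice=config.var_practice,
        cov_farm=np.asarray(config.cov_farm, dtype=float),
        var_calf_residual=config.var_calf_residual,
        practice_effects=v,
        farm_effects=u,
        farm_practice=farm_practice,
        calf_farm=calf_farm,
        short_window_farms=np.flatnonzero(short_mask),
        corruption_tallies=tallies,
        record_flags=flags,
    )
    return records, truth


def desk_config(**overrides) -> SimulationConfig:
    """A reduced-scale configuration for interactive and test runs.

    10 practices, 60 farms, 3,000 calves -- small enough to simulate and
    fit in minutes on one CPU while preserving the hierarchy's shape.
    """
    cfg = SimulationConfig(n_practices=10, n_farms=60, n_calves=3000)
    return dataclasses.replace(cfg, **overrides)
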