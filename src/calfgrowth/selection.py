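"""Record-selection cascade with per-stage inclusion reporting.

The cascade mirrors the cleaning applied to the source weight-recording
database before modelling, as an ordered sequence of individually
testable filters:

1. ``apply_age_window``    -- keep follow-up records with plausible ages
                              (default 1-138 days).
2. ``apply_farm_activity`` -- drop farms whose recording calendar spans
                              a year or less (default span > 365 days
                              required), i.e. farms without sustained
                              monitoring.
3. ``remove_estimates``    -- drop weights entered as estimates.
4. ``append_birth_records``-- inject confirmed birth weights as age-0
                              records for calves still present.
5. ``apply_weight_bounds`` -- keep weights in (30, 225] kg; applied
                              last so injected birth weights are
                              range-checked too.

``run_selection`` chains the filters and returns a
:class:`SelectionReport` with distinct-practice / farm / calf counts and
the record count after every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from calfgrowth import reference


@dataclass
class SelectionConfig:
    min_age_days: int = reference.AGE_MIN
    max_age_days: int = reference.AGE_MAX
    min_activity_span_days: int = 365  # farms must span MORE than this
    weight_lower_exclusive: float = reference.WEIGHT_LOWER_EXCLUSIVE
    weight_upper_inclusive: float = reference.WEIGHT_UPPER_INCLUSIVE
    drop_estimates: bool = True

    def validate(self) -> None:
        if self.min_age_days > self.max_age_days:
            raise ValueError("min_age_days exceeds max_age_days")
        if self.weight_lower_exclusive >= self.weight_upper_inclusive:
            raise ValueError("weight bounds are not ordered")


@dataclass
class StageCounts:
    stage: str
    practices: int
    farms: int
    calves: int
    recordings: int


@dataclass
class SelectionReport:
    """Ordered per-stage inclusion counts, one row per cascade stage."""

    stages: list[StageCounts] = field(default_factory=list)

    def add(self, stage: str, records: pd.DataFrame) -> None:
        self.stages.append(
            StageCounts(
                stage=stage,
                practices=int(records["practice_id"].nunique()),
                farms=int(records["farm_id"].nunique()),
                calves=int(records["calf_id"].nunique()),
                recordings=int(len(records)),
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "practices": s.practices,
                    "farms": s.farms,
                    "calves": s.calves,
                    "recordings": s.recordings,
                }
                for s in self.stages
            ]
        )


def apply_age_window(
    records: pd.DataFrame,
    min_age: int = reference.AGE_MIN,
    max_age: int = reference.AGE_MAX,
) -> pd.DataFrame:
    """Keep records with ``min_age <= age_days <= max_age``.

    Records with missing or negative ages are dropped, not errors:
    implausible ages are exactly what this filter exists to remove.
    """
    if min_age > max_age:
        raise ValueError("min_age exceeds max_age")
    age = records["age_days"]
    keep = age.notna() & (age >= min_age) & (age <= max_age)
    return records.loc[keep]


def apply_farm_activity(
    records: pd.DataFrame, min_span_days: int = 365
) -> pd.DataFrame:
    """Drop all records of farms whose recording span is <= ``min_span_days``.

    The span is last minus first ``recording_date`` per farm, so a farm
    with a single recording (span 0) is always dropped.
    """
    if len(records) == 0:
        return records
    dates = records.groupby("farm_id")["recording_date"]
    span = (dates.max() - dates.min()).dt.days
    active = span.index[span > min_span_days]
    return records.loc[records["farm_id"].isin(active)]


def remove_estimates(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records not flagged as estimated weights."""
    return records.loc[~records["is_estimate"].astype(bool)]


def split_birth_weights(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate a raw table into follow-up records and a birth-weight table.

    Confirmed birth weights travel as rows flagged ``is_birth_weight``;
    the cascade consumes them separately (they are appended for calves
    that survive the earlier filters).  Returns
    ``(follow_up_records, birth_weights)`` where the second frame has
    one row per calf with columns ``calf_id``, ``weight_kg``,
    ``birth_date``.
    """
    mask = records["is_birth_weight"].astype(bool)
    births = records.loc[
        mask,
        ["calf_id", "weight_kg", "birth_date", "farm_id", "practice_id"],
    ]
    dup = births["calf_id"].duplicated()
    if dup.any():
        births = births.loc[~dup]
    return records.loc[~mask], births.reset_index(drop=True)


def append_birth_records(
    records: pd.DataFrame, birth_weights: pd.DataFrame
) -> pd.DataFrame:
    """Append confirmed birth weights as age-0 records for present calves.

    ``birth_weights`` has one row per calf (``calf_id``, ``weight_kg``,
    ``birth_date``); duplicates keep the first occurrence.  Calves not
    present in ``records`` gain no record -- the birth weight of an
    otherwise-excluded calf is not re-admitted.
    """
    if len(records) == 0 or len(birth_weights) == 0:
        return records
    births = birth_weights.loc[~birth_weights["calf_id"].duplicated()]
    births = births[births["calf_id"].isin(records["calf_id"].unique())]
    # a calf that already carries a birth record keeps it unchanged
    existing = records.loc[
        records["is_birth_weight"].astype(bool), "calf_id"
    ].unique()
    births = births[~births["calf_id"].isin(existing)]
    if len(births) == 0:
        return records
    keys = records.drop_duplicates("calf_id")[
        ["practice_id", "farm_id", "calf_id"]
    ]
    new = births[["calf_id", "weight_kg", "birth_date"]].merge(
        keys, on="calf_id", how="left"
    )
    new["recording_date"] = new["birth_date"]
    new["age_days"] = 0
    new["is_estimate"] = False
    new["is_birth_weight"] = True
    out = pd.concat([records, new[records.columns]], ignore_index=True)
    return out.sort_values(
        ["practice_id", "farm_id", "calf_id", "age_days"], kind="stable"
    ).reset_index(drop=True)


def apply_weight_bounds(
    records: pd.DataFrame,
    lower_exclusive: float = reference.WEIGHT_LOWER_EXCLUSIVE,
    upper_inclusive: float = reference.WEIGHT_UPPER_INCLUSIVE,
) -> pd.DataFrame:
    """Keep records with ``lower_exclusive < weight_kg <= upper_inclusive``."""
    if lower_exclusive >= upper_inclusive:
        raise ValueError("weight bounds are not ordered")
    w = records["weight_kg"]
    return records.loc[(w > lower_exclusive) & (w <= upper_inclusive)]


def run_selection(
    records: pd.DataFrame,
    birth_weights: pd.DataFrame | None = None,
    config: SelectionConfig | None = None,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Run the full cascade and report per-stage inclusion counts.

    If ``birth_weights`` is ``None`` and the input carries
    ``is_birth_weight`` rows, those rows are split out first and used as
    the confirmed-birth-weight table.
    """
    config = config or SelectionConfig()
    config.validate()
    if birth_weights is None:
        records, birth_weights = split_birth_weights(records)

    report = SelectionReport()
    report.add("input", records)

    records = apply_age_window(records, config.min_age_days, config.max_age_days)
    report.add(
        f"age {config.min_age_days}-{config.max_age_days} d", records
    )

    records = apply_farm_activity(records, config.min_activity_span_days)
    report.add(
        f"farm span > {config.min_activity_span_days} d", records
    )
    surviving_farms = set(records["farm_id"].unique())

    if config.drop_estimates:
        records = remove_estimates(records)
        report.add("estimates removed", records)

    records = append_birth_records(records, birth_weights)
    # calves whose only measurement is a confirmed birth weight stay in
    # the study when their farm passed the activity filter
    if "farm_id" in birth_weights.columns and len(birth_weights):
        orphans = birth_weights.loc[
            birth_weights["farm_id"].isin(surviving_farms)
            & ~birth_weights["calf_id"].isin(records["calf_id"].unique())
        ].copy()
        if len(orphans):
            orphans["recording_date"] = orphans["birth_date"]
            orphans["age_days"] = 0
            orphans["is_estimate"] = False
            orphans["is_birth_weight"] = True
            records = (
                pd.concat(
                    [records, orphans[list(records.columns)]],
                    ignore_index=True,
                )
                .sort_values(
                    ["practice_id", "farm_id", "calf_id", "age_days"],
                    kind="stable",
                )
                .reset_index(drop=True)
            )
    report.add("birth weights appended", records)

    records = apply_weight_bounds(
        records, config.weight_lower_exclusive, config.weight_upper_inclusive
    )
    report.add(
        f"weight ({config.weight_lower_exclusive:g}, "
        f"{config.weight_upper_inclusive:g}] kg",
        records,
    )
    return records.reset_index(drop=True), report
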