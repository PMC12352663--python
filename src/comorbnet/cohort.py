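"""Cohort data model, CSV I/O, and the inclusion filters defining the analysis cohort.

The analysis unit is a dog with six demographic covariates (age, weight,
four-level sex/sterilization status encoded as three dummies, and
purebred/mixed breed background), a set of lifetime health conditions, and
owner-reported onset dates for a subset of those conditions.  Conditions are
catalogued with a display name and a body-system category.

Inclusion filters mirror the study design: conditions reported by fewer than
``min_dogs`` dogs are dropped (one-in-ten rule for six-predictor logistic
models), then dogs left with no retained condition are dropped.  The
condition filter is applied exactly once, on the full cohort — there is no
re-filtering loop after dog removal, so a condition may legally sit below
threshold in the final cohort.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "SEX_LEVELS",
    "BREED_LEVELS",
    "DogRecord",
    "ConditionCatalog",
    "Cohort",
    "DogHistory",
    "SchemaError",
    "DataError",
    "read_cohort",
    "write_cohort",
    "filter_conditions",
    "filter_dogs",
    "compute_history",
]

SEX_LEVELS = ("intact_female", "spayed_female", "intact_male", "neutered_male")
BREED_LEVELS = ("purebred", "mixed")

DOGS_COLUMNS = ("dog_id", "age_years", "weight_lbs", "sex_status", "breed_background")
EVENTS_COLUMNS = ("dog_id", "condition_id", "onset_date")
CATALOG_COLUMNS = ("condition_id", "condition_name", "category")


class SchemaError(ValueError):
    """An input table is missing a required column or has an invalid layout."""


class DataError(ValueError):
    """A row-level problem: bad date, unknown id, duplicate event."""


@dataclass
class DogRecord:
    """One dog: covariates, lifetime condition set, and dated onsets.

    ``onset_dates`` maps a subset of ``conditions`` to calendar dates; a
    condition with no reported onset still counts for co-occurrence but is
    excluded from temporal computations.  ``onset_precision`` records whether
    each date was reported to the day or imputed from a month-level report.
    """

    dog_id: str
    age: float
    weight: float
    sex_status: str
    breed_background: str
    conditions: set = field(default_factory=set)
    onset_dates: dict = field(default_factory=dict)
    onset_precision: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"dog {self.dog_id}: age must be >= 0, got {self.age}")
        if self.weight <= 0:
            raise ValueError(f"dog {self.dog_id}: weight must be > 0, got {self.weight}")
        if self.sex_status not in SEX_LEVELS:
            raise ValueError(
                f"dog {self.dog_id}: sex_status {self.sex_status!r} not in {SEX_LEVELS}"
            )
        if self.breed_background not in BREED_LEVELS:
            raise ValueError(
                f"dog {self.dog_id}: breed_background {self.breed_background!r} "
                f"not in {BREED_LEVELS}"
            )
        extra = set(self.onset_dates) - self.conditions
        if extra:
            raise ValueError(
                f"dog {self.dog_id}: onset dates for conditions not in the "
                f"condition set: {sorted(extra)}"
            )


@dataclass
class ConditionCatalog:
    """Condition metadata plus prevalence counts in the current cohort.

    ``table`` is indexed by condition_id with columns ``condition_name``,
    ``category`` and ``prevalence_count``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            dup = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate condition ids in catalog: {dup}")
        if (self.table["prevalence_count"] < 0).any():
            raise ValueError("negative prevalence count in catalog")

    @property
    def condition_ids(self) -> list:
        return list(self.table.index)

    def __contains__(self, condition_id) -> bool:
        return condition_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def name(self, condition_id) -> str:
        return self.table.at[condition_id, "condition_name"]

    def category(self, condition_id) -> str:
        return self.table.at[condition_id, "category"]

    def count(self, condition_id) -> int:
        return int(self.table.at[condition_id, "prevalence_count"])


@dataclass
class Cohort:
    """The analysis cohort: dogs plus the condition catalog with counts."""

    dogs: list
    catalog: ConditionCatalog

    @property
    def N(self) -> int:
        return len(self.dogs)

    def recount(self) -> "Cohort":
        """Return a cohort whose catalog counts are recomputed from the dogs."""
        counts = {cid: 0 for cid in self.catalog.condition_ids}
        for dog in self.dogs:
            for cid in dog.conditions:
                if cid in counts:
                    counts[cid] += 1
        table = self.catalog.table.copy()
        table["prevalence_count"] = [counts[cid] for cid in table.index]
        return Cohort(self.dogs, ConditionCatalog(table))

    def validate(self) -> None:
        """Check internal consistency: counts match dogs; conditions known."""
        recounted = self.recount()
        a = self.catalog.table["prevalence_count"]
        b = recounted.catalog.table["prevalence_count"]
        if not a.equals(b):
            bad = a.index[a != b].tolist()
            raise ValueError(f"catalog prevalence counts stale for: {bad}")
        known = set(self.catalog.condition_ids)
        for dog in self.dogs:
            unknown = dog.conditions - known
            if unknown:
                raise ValueError(
                    f"dog {dog.dog_id} has conditions absent from catalog: "
                    f"{sorted(unknown)}"
                )

    def condition_indicators(self):
        """Binary indicator matrix (dogs x conditions) and both index orders."""
        import numpy as np

        cids = self.catalog.condition_ids
        pos = {cid: j for j, cid in enumerate(cids)}
        X = np.zeros((self.N, len(cids)), dtype=bool)
        for i, dog in enumerate(self.dogs):
            for cid in dog.conditions:
                X[i, pos[cid]] = True
        dog_ids = [d.dog_id for d in self.dogs]
        return X, dog_ids, cids


@dataclass(frozen=True)
class DogHistory:
    """Medical-history span: earliest to latest reported onset, in days."""

    dog_id: str
    first_onset: _dt.date
    last_onset: _dt.date

    @property
    def span_days(self) -> int:
        return (self.last_onset - self.first_onset).days


def _parse_onset(raw: str, line_no: int, path) -> tuple:
    """Parse YYYY-MM-DD, or YYYY-MM imputed to day 15 (flagged 'month')."""
    raw = raw.strip()
    try:
        if len(raw) == 7:
            d = _dt.datetime.strptime(raw, "%Y-%m").date().replace(day=15)
            return d, "month"
        d = _dt.datetime.strptime(raw, "%Y-%m-%d").date()
        return d, "day"
    except ValueError:
        raise DataError(
            f"{path}, line {line_no}: unparseable onset date {raw!r} "
            f"(expected YYYY-MM-DD or YYYY-MM)"
        ) from None


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_cohort(dogs_path, events_path, catalog_path) -> Cohort:
    """Read and validate a cohort from the three CSV inputs.

    Events referencing unknown dogs or conditions, unparseable dates and
    duplicate (dog, condition) events are hard errors: surveys should not
    emit them, and silent repair would hide upstream data bugs.
    """
    dogs_df = pd.read_csv(dogs_path, dtype={"dog_id": str})
    _require_columns(dogs_df, DOGS_COLUMNS, dogs_path)
    catalog_df = pd.read_csv(catalog_path, dtype=str)
    _require_columns(catalog_df, CATALOG_COLUMNS, catalog_path)
    events_df = pd.read_csv(events_path, dtype=str)
    _require_columns(events_df, EVENTS_COLUMNS, events_path)

    dogs: dict = {}
    for row in dogs_df.itertuples(index=False):
        if row.dog_id in dogs:
            raise DataError(f"{dogs_path}: duplicate dog_id {row.dog_id!r}")
        dogs[row.dog_id] = DogRecord(
            dog_id=row.dog_id,
            age=float(row.age_years),
            weight=float(row.weight_lbs),
            sex_status=row.sex_status,
            breed_background=row.breed_background,
        )

    known_conditions = set(catalog_df["condition_id"])
    seen_events = set()
    duplicates = []
    for line_no, row in enumerate(events_df.itertuples(index=False), start=2):
        if row.dog_id not in dogs:
            raise DataError(
                f"{events_path}, line {line_no}: unknown dog_id {row.dog_id!r}"
            )
        if row.condition_id not in known_conditions:
            raise DataError(
                f"{events_path}, line {line_no}: condition_id "
                f"{row.condition_id!r} absent from catalog"
            )
        key = (row.dog_id, row.condition_id)
        if key in seen_events:
            duplicates.append(key)
            continue
        seen_events.add(key)
        dog = dogs[row.dog_id]
        dog.conditions.add(row.condition_id)
        raw = row.onset_date
        if isinstance(raw, str) and raw.strip():
            date, precision = _parse_onset(raw, line_no, events_path)
            dog.onset_dates[row.condition_id] = date
            dog.onset_precision[row.condition_id] = precision
    if duplicates:
        raise DataError(
            f"{events_path}: duplicate (dog, condition) events: {duplicates}"
        )

    table = catalog_df.set_index("condition_id")[["condition_name", "category"]]
    table["prevalence_count"] = 0
    cohort = Cohort(list(dogs.values()), ConditionCatalog(table)).recount()
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, dogs_path, events_path, catalog_path) -> None:
    """Write the three CSVs; inverse of :func:`read_cohort`."""
    dogs_rows = [
        {
            "dog_id": d.dog_id,
            "age_years": d.age,
            "weight_lbs": d.weight,
            "sex_status": d.sex_status,
            "breed_background": d.breed_background,
        }
        for d in cohort.dogs
    ]
    pd.DataFrame(dogs_rows, columns=list(DOGS_COLUMNS)).to_csv(dogs_path, index=False)

    event_rows = []
    for d in cohort.dogs:
        for cid in sorted(d.conditions):
            date = d.onset_dates.get(cid)
            if date is not None and d.onset_precision.get(cid) == "month":
                raw = date.strftime("%Y-%m")
            elif date is not None:
                raw = date.isoformat()
            else:
                raw = ""
            event_rows.append(
                {"dog_id": d.dog_id, "condition_id": cid, "onset_date": raw}
            )
    pd.DataFrame(event_rows, columns=list(EVENTS_COLUMNS)).to_csv(
        events_path, index=False
    )

    cat = cohort.catalog.table.reset_index()[
        ["condition_id", "condition_name", "category"]
    ]
    cat.to_csv(catalog_path, index=False)


def filter_conditions(cohort: Cohort, min_dogs: int) -> Cohort:
    """Drop conditions reported by fewer than ``min_dogs`` dogs.

    Single pass on the cohort as given; counts are taken from the current
    catalog, and retained conditions are removed from every dog's set.
    """
    if min_dogs < 1:
        raise ValueError("min_dogs must be >= 1")
    cohort = cohort.recount()
    keep = set(
        cohort.catalog.table.index[
            cohort.catalog.table["prevalence_count"] >= min_dogs
        ]
    )
    new_dogs = [
        replace(
            d,
            conditions=d.conditions & keep,
            onset_dates={c: v for c, v in d.onset_dates.items() if c in keep},
            onset_precision={
                c: v for c, v in d.onset_precision.items() if c in keep
            },
        )
        for d in cohort.dogs
    ]
    table = cohort.catalog.table.loc[cohort.catalog.table.index.isin(keep)].copy()
    return Cohort(new_dogs, ConditionCatalog(table)).recount()


def filter_dogs(cohort: Cohort) -> Cohort:
    """Drop dogs with no retained conditions; recompute counts."""
    kept = [d for d in cohort.dogs if d.conditions]
    return Cohort(kept, ConditionCatalog(cohort.catalog.table.copy())).recount()


def compute_history(dog: DogRecord) -> DogHistory:
    """Medical-history span from the dog's dated onsets (all conditions).

    Span is last minus first reported onset; zero for a single dated onset.
    """
    dates = list(dog.onset_dates.values())
    if not dates:
        raise ValueError(f"dog {dog.dog_id} has no dated onsets")
    return DogHistory(dog.dog_id, min(dates), max(dates))
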