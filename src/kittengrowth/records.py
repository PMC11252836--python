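"""Domain records: one kitten per row, plus the breed threshold table.

A kitten is the analysis unit: identity, daily weights over the first week
(Day 0 = birth, grams), survival status at 2 months and, when known, the day
of death. Birth-weight category (LBW/NBW) is assigned against a breed-specific
threshold: strictly below the threshold is low birth weight.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import BreedLookupError, RowValidationError, SchemaError

#: Weighing days covered by the record (Day 0 .. Day 7).
DAYS = tuple(range(8))

#: Survival horizon in days ("2 months").
HORIZON_DAYS = 60


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Status(str, Enum):
    ALIVE = "alive"
    DEAD = "dead"
    UNKNOWN = "unknown"


class BwCategory(str, Enum):
    LBW = "LBW"
    NBW = "NBW"
    UNASSIGNED = "unassigned"


@dataclass
class KittenRecord:
    """One kitten's identity, weights and outcome.

    ``weights`` maps day (0-7) to grams; Day 0 is required, later days are
    optional. ``death_day`` is only meaningful for dead kittens and must lie
    within the 0-60 day horizon.
    """

    kitten_id: str
    litter_id: str
    breed: str
    sex: Sex
    weights: dict[int, float]
    status_2mo: Status
    death_day: int | None = None
    bw_category: BwCategory = BwCategory.UNASSIGNED

    def __post_init__(self) -> None:
        for day, w in self.weights.items():
            if day not in DAYS:
                raise RowValidationError(f"weight day {day} outside 0-7", field=f"w{day}")
            if not (w > 0):
                raise RowValidationError(
                    f"weight on day {day} must be strictly positive, got {w}",
                    field=f"w{day}",
                )
        if 0 not in self.weights:
            raise RowValidationError("birth weight missing", field="w0")
        if self.death_day is not None:
            if self.status_2mo is not Status.DEAD:
                raise RowValidationError(
                    "death_day present but status is not dead", field="death_day"
                )
            if not (0 <= self.death_day <= HORIZON_DAYS):
                raise RowValidationError(
                    f"death_day {self.death_day} outside the 0-{HORIZON_DAYS} day horizon",
                    field="death_day",
                )

    @property
    def birth_weight(self) -> float:
        return self.weights[0]

    def weight(self, day: int) -> float | None:
        return self.weights.get(day)

    def with_category(self, category: BwCategory) -> "KittenRecord":
        return replace(self, bw_category=category)


@dataclass(frozen=True)
class BreedThresholdTable:
    """Breed -> low-birth-weight threshold (grams).

    Lookup of a breed absent from the table is an error, never a default:
    misclassifying against the wrong breed's threshold is worse than failing.
    """

    thresholds: Mapping[str, float]

    def __post_init__(self) -> None:
        for breed, t in self.thresholds.items():
            if not (t > 0):
                raise ValueError(f"threshold for breed {breed!r} must be positive, got {t}")

    def threshold(self, breed: str) -> float:
        try:
            return self.thresholds[breed]
        except KeyError:
            raise BreedLookupError(
                f"breed {breed!r} has no entry in the threshold table"
            ) from None

    @classmethod
    def read_csv(cls, path: str | Path) -> "BreedThresholdTable":
        path = Path(path)
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            cols = reader.fieldnames or []
            if "breed" not in cols or "lbw_threshold_g" not in cols:
                raise SchemaError(
                    f"{path}: expected columns breed,lbw_threshold_g; got {cols}"
                )
            table = {}
            for row in reader:
                try:
                    table[row["breed"]] = float(row["lbw_threshold_g"])
                except ValueError:
                    raise SchemaError(
                        f"{path}: non-numeric threshold for breed {row['breed']!r}"
                    ) from None
        return cls(table)

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["breed", "lbw_threshold_g"])
            for breed, t in self.thresholds.items():
                writer.writerow([breed, repr(float(t))])


@dataclass
class SelectionLog:
    """Outcome of a cohort selection pass: retained records plus per-record
    exclusion reasons, preserving input order within each part."""

    retained: list[KittenRecord]
    excluded: list[tuple[KittenRecord, str]] = field(default_factory=list)

    @property
    def reasons(self) -> list[str]:
        return [reason for _, reason in self.excluded]


def iter_litters(records: Iterable[KittenRecord]):
    """Group records by litter_id, preserving first-seen litter order."""
    by_litter: dict[str, list[KittenRecord]] = {}
    for rec in records:
        by_litter.setdefault(rec.litter_id, []).append(rec)
    return by_litter.items()
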