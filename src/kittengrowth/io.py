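"""Cohort table IO and the selection flow.

The cohort file is a flat CSV, one row per kitten:

    kitten_id,litter_id,breed,sex,w0,...,w7,status_2mo,death_day

Weights are grams with dot decimals; blank cells are missing. ``read_cohort``
validates each row and reports rejects by row number instead of aborting the
whole file; ``apply_selection`` implements the study's first selection round
(known 2-month status, birth weight present); ``classify_birth_weight``
assigns LBW strictly below the breed threshold and NBW otherwise.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from .errors import RowValidationError, SchemaError
from .records import (
    DAYS,
    BreedThresholdTable,
    BwCategory,
    KittenRecord,
    SelectionLog,
    Sex,
    Status,
)

WEIGHT_COLUMNS = tuple(f"w{d}" for d in DAYS)
COLUMNS = ("kitten_id", "litter_id", "breed", "sex", *WEIGHT_COLUMNS, "status_2mo", "death_day")


def _parse_row(row: dict[str, str]) -> KittenRecord:
    weights: dict[int, float] = {}
    for d in DAYS:
        cell = (row.get(f"w{d}") or "").strip()
        if not cell:
            continue
        try:
            weights[d] = float(cell)
        except ValueError:
            raise RowValidationError(
                f"non-numeric weight {cell!r} in w{d}", field=f"w{d}"
            ) from None
    sex_cell = (row.get("sex") or "").strip().lower() or "unknown"
    try:
        sex = Sex(sex_cell)
    except ValueError:
        raise RowValidationError(f"unknown sex {sex_cell!r}", field="sex") from None
    status_cell = (row.get("status_2mo") or "").strip().lower() or "unknown"
    try:
        status = Status(status_cell)
    except ValueError:
        raise RowValidationError(
            f"unknown status {status_cell!r}", field="status_2mo"
        ) from None
    death_cell = (row.get("death_day") or "").strip()
    death_day = None
    if death_cell:
        try:
            death_day = int(float(death_cell))
        except ValueError:
            raise RowValidationError(
                f"non-numeric death_day {death_cell!r}", field="death_day"
            ) from None
    return KittenRecord(
        kitten_id=row["kitten_id"],
        litter_id=row["litter_id"],
        breed=row["breed"],
        sex=sex,
        weights=weights,
        status_2mo=status,
        death_day=death_day,
    )


def read_cohort(path: str | Path) -> tuple[list[KittenRecord], list[tuple[int, str]]]:
    """Read a cohort CSV.

    Returns ``(records, rejects)`` where rejects are ``(row_number, reason)``
    pairs, row numbers 1-based over data rows. A missing required column is a
    :class:`SchemaError`; bad cells reject the single row only.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    records: list[KittenRecord] = []
    rejects: list[tuple[int, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        for i, row in enumerate(reader, start=1):
            try:
                records.append(_parse_row(row))
            except RowValidationError as err:
                rejects.append((i, str(err)))
    return records, rejects


def write_cohort(records: Iterable[KittenRecord], path: str | Path) -> None:
    """Write records back to the cohort CSV schema.

    Floats are written with ``repr`` so a read/write cycle round-trips weights
    bit-identically.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for rec in records:
            row = [rec.kitten_id, rec.litter_id, rec.breed, rec.sex.value]
            for d in DAYS:
                w = rec.weights.get(d)
                row.append("" if w is None else repr(float(w)))
            row.append(rec.status_2mo.value)
            row.append("" if rec.death_day is None else str(rec.death_day))
            writer.writerow(row)


def apply_selection(records: Sequence[KittenRecord]) -> SelectionLog:
    """First selection round: keep kittens with a birth weight and a known
    2-month status. A pure filter — the retained and excluded lists partition
    the input, and the operation is idempotent."""
    log = SelectionLog(retained=[])
    for rec in records:
        if 0 not in rec.weights:
            log.excluded.append((rec, "birth weight missing"))
        elif rec.status_2mo is Status.UNKNOWN:
            log.excluded.append((rec, "status at 2 months unknown"))
        else:
            log.retained.append(rec)
    return log


def classify_birth_weight(record: KittenRecord, table: BreedThresholdTable) -> BwCategory:
    """LBW iff birth weight is strictly below the breed threshold; weight
    exactly at the threshold is NBW."""
    return (
        BwCategory.LBW
        if record.birth_weight < table.threshold(record.breed)
        else BwCategory.NBW
    )


def classify_cohort(
    records: Sequence[KittenRecord], table: BreedThresholdTable
) -> list[KittenRecord]:
    """Return new records with ``bw_category`` assigned for the whole cohort."""
    return [rec.with_category(classify_birth_weight(rec, table)) for rec in records]
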