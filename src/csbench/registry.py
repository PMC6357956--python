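"""Delivery-registry data model, readers/writers, validation and aggregation.

Two tabular layouts are supported, both UTF-8 comma-separated with one
header row:

``records``
    One delivery per row: ``site_id, birth_location, caesarean, indication``
    plus six optional ``compl_<label>`` 0/1 columns for the life-saving
    complication flags.  ``indication`` must be non-empty exactly when
    ``caesarean`` is 1.

``summaries``
    One site per row: ``site_id, total_deliveries, facility_deliveries,
    caesarean_total`` followed by one count column per indication label.
    Duplicate site rows are rejected rather than silently merged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .errors import ParseError, ValidationError
from .taxonomy import (
    ALL_INDICATIONS,
    LIFE_SAVING_INDICATIONS,
    BirthLocation,
    IndicationCategory,
)

RECORD_BASE_COLUMNS = ["site_id", "birth_location", "caesarean", "indication"]
COMPLICATION_COLUMNS = [f"compl_{c.value}" for c in LIFE_SAVING_INDICATIONS]
SUMMARY_BASE_COLUMNS = [
    "site_id",
    "total_deliveries",
    "facility_deliveries",
    "caesarean_total",
]


@dataclass(frozen=True)
class DeliveryRecord:
    """One delivery: where it happened, mode, and the caesarean indication."""

    site_id: str
    birth_location: BirthLocation
    caesarean: bool
    indication: IndicationCategory | None = None
    complications: frozenset[IndicationCategory] = frozenset()

    def __post_init__(self) -> None:
        if self.caesarean and self.indication is None:
            raise ValidationError(
                f"site {self.site_id}: caesarean record lacks an indication"
            )
        if not self.caesarean and self.indication is not None:
            raise ValidationError(
                f"site {self.site_id}: indication recorded on a non-caesarean delivery"
            )
        if self.caesarean and not self.birth_location.is_facility:
            raise ValidationError(
                f"site {self.site_id}: caesarean recorded at a non-facility location"
            )
        bad = [c for c in self.complications if not c.life_saving]
        if bad:
            raise ValidationError(
                f"site {self.site_id}: non-life-saving complication flags {bad}"
            )


@dataclass(frozen=True)
class SiteSummary:
    """Per-site delivery counts with caesareans broken down by indication."""

    site_id: str
    total_deliveries: int
    facility_deliveries: int
    caesarean_total: int
    indication_counts: Mapping[IndicationCategory, int] = field(default_factory=dict)

    def count(self, indication: IndicationCategory) -> int:
        return int(self.indication_counts.get(indication, 0))

    @property
    def life_saving_total(self) -> int:
        return sum(self.count(c) for c in LIFE_SAVING_INDICATIONS)


def validate_summary(summary: SiteSummary) -> list[str]:
    """Return a list of invariant violations; empty means the summary is valid."""
    violations: list[str] = []
    s = summary
    for name in ("total_deliveries", "facility_deliveries", "caesarean_total"):
        if getattr(s, name) < 0:
            violations.append(f"{s.site_id}: {name} is negative")
    for cat, n in s.indication_counts.items():
        if n < 0:
            violations.append(f"{s.site_id}: negative count for {cat.value}")
    if s.facility_deliveries > s.total_deliveries:
        violations.append(
            f"{s.site_id}: facility_deliveries {s.facility_deliveries} exceeds "
            f"total_deliveries {s.total_deliveries}"
        )
    if s.caesarean_total > s.total_deliveries:
        violations.append(
            f"{s.site_id}: caesarean_total {s.caesarean_total} exceeds "
            f"total_deliveries {s.total_deliveries}"
        )
    indication_sum = sum(int(n) for n in s.indication_counts.values())
    if indication_sum != s.caesarean_total:
        violations.append(
            f"{s.site_id}: indication counts sum to {indication_sum}, "
            f"caesarean_total is {s.caesarean_total}"
        )
    return violations


def aggregate(records: Iterable[DeliveryRecord]) -> list[SiteSummary]:
    """Aggregate delivery records into one :class:`SiteSummary` per site.

    Sites appear in order of first occurrence; the indication counts of each
    summary partition its caesareans by construction.
    """
    acc: dict[str, dict] = {}
    for rec in records:
        site = acc.setdefault(
            rec.site_id,
            {"total": 0, "facility": 0, "cs": 0, "counts": dict.fromkeys(ALL_INDICATIONS, 0)},
        )
        site["total"] += 1
        if rec.birth_location.is_facility:
            site["facility"] += 1
        if rec.caesarean:
            site["cs"] += 1
            site["counts"][rec.indication] += 1
    return [
        SiteSummary(
            site_id=site_id,
            total_deliveries=a["total"],
            facility_deliveries=a["facility"],
            caesarean_total=a["cs"],
            indication_counts=a["counts"],
        )
        for site_id, a in acc.items()
    ]


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _parse_flag(text: str, row: int, column: str) -> bool:
    if text not in {"0", "1"}:
        raise ParseError(f"row {row}: column {column} must be 0 or 1, got {text!r}")
    return text == "1"


def _parse_count(text: str, row: int, column: str) -> int:
    try:
        value = int(text)
    except ValueError:
        raise ParseError(f"row {row}: column {column} is not an integer: {text!r}") from None
    return value


def _parse_indication(text: str, row: int) -> IndicationCategory | None:
    if text == "":
        return None
    try:
        return IndicationCategory(text)
    except ValueError:
        raise ParseError(f"row {row}: unknown indication label {text!r}") from None


def _read_rows(path: Path, required: Sequence[str]) -> tuple[list[str], list[dict]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise ParseError(f"{path}: header lacks required columns {missing}")
        rows = list(reader)
    for i, row in enumerate(rows, start=2):
        if any(v is None for v in row.values()) or None in row:
            raise ParseError(f"row {i}: wrong number of fields")
    return header, rows


def _records_from_rows(header: list[str], rows: list[dict]) -> list[DeliveryRecord]:
    compl_cols = [c for c in COMPLICATION_COLUMNS if c in header]
    records = []
    for i, row in enumerate(rows, start=2):
        try:
            location = BirthLocation(row["birth_location"])
        except ValueError:
            raise ParseError(
                f"row {i}: unknown birth_location {row['birth_location']!r}"
            ) from None
        caesarean = _parse_flag(row["caesarean"], i, "caesarean")
        indication = _parse_indication(row["indication"].strip(), i)
        complications = frozenset(
            IndicationCategory(col.removeprefix("compl_"))
            for col in compl_cols
            if _parse_flag(row[col] or "0", i, col)
        )
        try:
            records.append(
                DeliveryRecord(
                    site_id=row["site_id"],
                    birth_location=location,
                    caesarean=caesarean,
                    indication=indication,
                    complications=complications,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return records


def _summaries_from_rows(header: list[str], rows: list[dict]) -> list[SiteSummary]:
    seen: set[str] = set()
    summaries = []
    for i, row in enumerate(rows, start=2):
        site_id = row["site_id"]
        if site_id in seen:
            raise ParseError(f"row {i}: duplicate summary row for site {site_id!r}")
        seen.add(site_id)
        counts = {
            cat: _parse_count(row.get(cat.value, "0") or "0", i, cat.value)
            for cat in ALL_INDICATIONS
        }
        summaries.append(
            SiteSummary(
                site_id=site_id,
                total_deliveries=_parse_count(row["total_deliveries"], i, "total_deliveries"),
                facility_deliveries=_parse_count(
                    row["facility_deliveries"], i, "facility_deliveries"
                ),
                caesarean_total=_parse_count(row["caesarean_total"], i, "caesarean_total"),
                indication_counts=counts,
            )
        )
    return summaries


def read_registry(
    path: str | Path, layout: Literal["records", "summaries"]
) -> list[DeliveryRecord] | list[SiteSummary]:
    """Read a registry file in the given layout into validated objects."""
    path = Path(path)
    if layout == "records":
        header, rows = _read_rows(path, RECORD_BASE_COLUMNS)
        return _records_from_rows(header, rows)
    if layout == "summaries":
        header, rows = _read_rows(path, SUMMARY_BASE_COLUMNS)
        return _summaries_from_rows(header, rows)
    raise ValueError(f"unknown layout {layout!r}")


def write_registry(
    items: Sequence[DeliveryRecord] | Sequence[SiteSummary],
    path: str | Path,
    layout: Literal["records", "summaries"],
) -> None:
    """Write records or summaries back to the delimited layout read_registry expects."""
    path = Path(path)
    if layout == "records":
        fieldnames = RECORD_BASE_COLUMNS + COMPLICATION_COLUMNS
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(fieldnames)
            for rec in items:
                writer.writerow(
                    [
                        rec.site_id,
                        rec.birth_location.value,
                        int(rec.caesarean),
                        rec.indication.value if rec.indication else "",
                    ]
                    + [int(c in rec.complications) for c in LIFE_SAVING_INDICATIONS]
                )
    elif layout == "summaries":
        fieldnames = SUMMARY_BASE_COLUMNS + [c.value for c in ALL_INDICATIONS]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(fieldnames)
            for s in items:
                writer.writerow(
                    [s.site_id, s.total_deliveries, s.facility_deliveries, s.caesarean_total]
                    + [s.count(c) for c in ALL_INDICATIONS]
                )
    else:
        raise ValueError(f"unknown layout {layout!r}")
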