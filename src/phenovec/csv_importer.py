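"""Convert a flat CSV table into comparable records plus a descriptor.

Each row becomes one record whose body maps column name -> cell value;
cells holding a missing-value token emit no key at all (so missingness is
never counted as agreement), and multivalued cells are split on a
configurable separator.  The generated ``generic`` descriptor lists every
retained column as an allowed term, so flattening yields keys of the form
``Column.Value``.

Continuous numeric columns pass through as literal value keys; since two
ages of 41 and 42 then share nothing, a warning recommends binning such
columns into ranges/categories beforehand.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import ValidationError
from .formats_io import FormatDescriptor, RawRecord

log = logging.getLogger(__name__)

DEFAULT_NA_TOKENS: tuple[str, ...] = ("NA", "", "unknown", "missing")


@dataclass(frozen=True)
class CsvImportConfig:
    id_column: str
    na_tokens: tuple[str, ...] = DEFAULT_NA_TOKENS
    multivalue_separator: str = ";"
    included_columns: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.multivalue_separator) != 1:
            raise ValidationError("multivalue separator must be a single character")


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


def import_csv(
    path: str | Path, config: CsvImportConfig
) -> tuple[list[RawRecord], FormatDescriptor]:
    """Read ``path`` (RFC 4180 CSV with header) into records + descriptor.

    Rows are never dropped, only missing cells.  Raises
    :class:`ValidationError` on a missing id column, duplicate ids, or
    ragged rows.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file, no header") from None
        if config.id_column not in header:
            raise ValidationError(
                f"{path}: id column {config.id_column!r} not in header "
                f"({', '.join(header)})"
            )
        columns = [
            c
            for c in header
            if config.included_columns is None
            or c in config.included_columns
            or c == config.id_column
        ]
        id_idx = header.index(config.id_column)

        records: list[RawRecord] = []
        seen: dict[str, int] = {}
        numeric_candidates = {c: True for c in columns if c != config.id_column}
        has_values = {c: False for c in columns if c != config.id_column}
        for row_no, row in enumerate(reader):
            if len(row) != len(header):
                raise ValidationError(
                    f"{path}: row {row_no + 2} has {len(row)} cells, "
                    f"expected {len(header)}"
                )
            rid = row[id_idx].strip()
            if rid == "":
                raise ValidationError(f"{path}: row {row_no + 2} has an empty id")
            if rid in seen:
                raise ValidationError(
                    f"{path}: duplicate id {rid!r} at row {row_no + 2}"
                )
            seen[rid] = row_no
            body: dict = {config.id_column: rid}
            for col, cell in zip(header, row):
                if col not in columns or col == config.id_column:
                    continue
                values = [
                    v.strip()
                    for v in cell.split(config.multivalue_separator)
                    if v.strip() not in config.na_tokens
                ]
                if not values:
                    continue
                has_values[col] = True
                if not all(_is_number(v) for v in values):
                    numeric_candidates[col] = False
                body[col] = values if len(values) > 1 else values[0]
            records.append(RawRecord(id=rid, body=body))

    if not records:
        log.warning("%s: header-only CSV, empty cohort", path)
    for col, numeric in numeric_candidates.items():
        if numeric and has_values[col]:
            log.warning(
                "column %r looks numeric/continuous; consider binning it into "
                "ranges or categories before comparison",
                col,
            )

    descriptor = FormatDescriptor(
        format_name="generic",
        id_path=config.id_column,
        allowed_terms=tuple(columns),
        exclude_paths=(config.id_column,),
    )
    return records, descriptor
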