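"""Delimited-text registry I/O with a configurable column/enum dialect.

The real nationwide registry export format is not publicly documented, so the
column names, enum encodings and missing-value codes live in a user-editable
dialect configuration (YAML or JSON).  The shipped default is a plain UTF-8
CSV with canonical field names and lowercase enum values; any cell that fails
to parse becomes the missing state rather than a default value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional, Union

import pandas as pd
import yaml

from .records import (
    FIELD_NAMES,
    Cause,
    Cpc,
    FirstRhythm,
    Region,
    UtsteinRecord,
)


class DialectError(ValueError):
    """A dialect/file mismatch, e.g. a required column absent from the header."""


class RegistryValidationError(ValueError):
    """Structurally invalid registry content, e.g. duplicate record ids."""


_TRUE_CODES = {"1", "true", "yes", "y"}
_FALSE_CODES = {"0", "false", "no", "n"}


def _default_enum_maps() -> dict[str, dict[str, str]]:
    return {
        "cause": {c.value: c.value for c in Cause},
        "first_rhythm": {r.value: r.value for r in FirstRhythm},
        "region": {r.value: r.value for r in Region},
    }


@dataclass
class Dialect:
    """How a delimited registry export encodes the canonical record fields.

    ``columns`` maps canonical field name -> column header in the file;
    ``enum_maps`` maps canonical field name -> {file code -> canonical enum
    value}; ``missing_codes`` are cell values treated as missing everywhere.
    """

    delimiter: str = ","
    columns: dict[str, str] = field(
        default_factory=lambda: {name: name for name in FIELD_NAMES}
    )
    enum_maps: dict[str, dict[str, str]] = field(default_factory=_default_enum_maps)
    missing_codes: tuple[str, ...] = ("", "NA", "NaN", "null", "missing")

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "Dialect":
        base = cls()
        if "delimiter" in data:
            base.delimiter = str(data["delimiter"])
        if "columns" in data:
            base.columns.update({str(k): str(v) for k, v in data["columns"].items()})
        if "enum_maps" in data:
            for fname, mapping in data["enum_maps"].items():
                base.enum_maps.setdefault(fname, {}).update(
                    {str(k): str(v) for k, v in mapping.items()}
                )
        if "missing_codes" in data:
            base.missing_codes = tuple(str(c) for c in data["missing_codes"])
        return base

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "Dialect":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_mapping(data or {})

    # -- cell-level parsing ------------------------------------------------

    def _is_missing(self, cell: Optional[str]) -> bool:
        return cell is None or cell.strip() in self.missing_codes

    def parse_bool(self, cell: Optional[str]) -> Optional[bool]:
        if self._is_missing(cell):
            return None
        token = cell.strip().lower()
        if token in _TRUE_CODES:
            return True
        if token in _FALSE_CODES:
            return False
        return None

    def parse_number(self, cell: Optional[str], kind: type) -> Optional[Any]:
        if self._is_missing(cell):
            return None
        try:
            value = float(cell.strip())
        except ValueError:
            return None
        if kind is int:
            return int(value) if value == int(value) else None
        return value

    def parse_enum(self, fname: str, cell: Optional[str], enum_cls: type) -> Any:
        if self._is_missing(cell):
            return None
        token = cell.strip()
        mapped = self.enum_maps.get(fname, {}).get(token, token)
        try:
            return enum_cls(mapped)
        except ValueError:
            return None

    def parse_cpc(self, cell: Optional[str]) -> Cpc:
        if self._is_missing(cell):
            return Cpc.UNKNOWN
        token = cell.strip().lower()
        if token == "unknown":
            return Cpc.UNKNOWN
        value = self.parse_number(cell, int)
        if value in (1, 2, 3, 4, 5):
            return Cpc(value)
        return Cpc.UNKNOWN


DEFAULT_DIALECT = Dialect()


def _record_from_row(row: pd.Series, dialect: Dialect) -> UtsteinRecord:
    def cell(fname: str) -> Optional[str]:
        return row[dialect.columns[fname]]

    witnessed = dialect.parse_bool(cell("witnessed"))
    no_flow = dialect.parse_number(cell("no_flow_time"), float)
    if witnessed is False:
        no_flow = None  # no-flow time is defined only for witnessed arrests
    age = dialect.parse_number(cell("age"), int)
    if age is not None and age < 0:
        age = None
    if no_flow is not None and no_flow < 0:
        no_flow = None
    return UtsteinRecord(
        record_id=str(cell("record_id")).strip(),
        age=age,
        cause=dialect.parse_enum("cause", cell("cause"), Cause),
        witnessed=witnessed,
        no_flow_time=no_flow,
        first_rhythm=dialect.parse_enum("first_rhythm", cell("first_rhythm"), FirstRhythm),
        pad_performed=dialect.parse_bool(cell("pad_performed")) or False,
        prehospital_rosc=dialect.parse_bool(cell("prehospital_rosc")) or False,
        resuscitation_attempted=dialect.parse_bool(cell("resuscitation_attempted")) or False,
        region=dialect.parse_enum("region", cell("region"), Region) or Region.OTHER,
        year=dialect.parse_number(cell("year"), int) or 0,
        cpc=dialect.parse_cpc(cell("cpc")),
    )


def parse_registry(
    file_path: Union[str, Path], dialect: Optional[Dialect] = None
) -> list[UtsteinRecord]:
    """Read a delimited registry export into :class:`UtsteinRecord` objects.

    One record per data row; unparseable cells become missing.  Raises
    :class:`DialectError` naming any required column absent from the header
    and :class:`RegistryValidationError` on duplicate record ids.
    """
    dialect = dialect or DEFAULT_DIALECT
    frame = pd.read_csv(
        file_path,
        sep=dialect.delimiter,
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )
    missing_cols = [
        col for col in dialect.columns.values() if col not in frame.columns
    ]
    if missing_cols:
        raise DialectError(f"required column(s) missing from header: {missing_cols}")
    records = [_record_from_row(row, dialect) for _, row in frame.iterrows()]
    seen: set[str] = set()
    for rec in records:
        if rec.record_id in seen:
            raise RegistryValidationError(f"duplicate record_id: {rec.record_id!r}")
        seen.add(rec.record_id)
    return records


def _format_cell(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, Cpc):
        return "unknown" if value is Cpc.UNKNOWN else str(value.value)
    if isinstance(value, (Cause, FirstRhythm, Region)):
        return value.value
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_records(
    records: Iterable[UtsteinRecord],
    file_path: Union[str, Path],
    dialect: Optional[Dialect] = None,
) -> None:
    """Write records as delimited text, the inverse of :func:`parse_registry`.

    Canonical enum codes are emitted (the default dialect round-trips them);
    column order follows the dialect's field order.
    """
    dialect = dialect or DEFAULT_DIALECT
    inverse_enum: dict[str, dict[str, str]] = {
        fname: {canon: code for code, canon in mapping.items()}
        for fname, mapping in dialect.enum_maps.items()
    }
    rows = []
    for rec in records:
        row = {}
        for fname in FIELD_NAMES:
            value = getattr(rec, fname)
            cell = _format_cell(value)
            if fname in inverse_enum and cell in inverse_enum[fname]:
                cell = inverse_enum[fname][cell]
            row[dialect.columns[fname]] = cell
        rows.append(row)
    frame = pd.DataFrame(rows, columns=[dialect.columns[f] for f in FIELD_NAMES])
    frame.to_csv(file_path, sep=dialect.delimiter, index=False, encoding="utf-8")
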