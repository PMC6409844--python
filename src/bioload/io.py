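"""Tidy-CSV readers and writers.

CSV is the single interchange format: concentrations as
``site,compartment,element,replicate,value_mg_per_g`` and backgrounds as
``element,background_mg_per_g``.  Column names are remappable through a
``schema`` mapping so files from other pipelines can be ingested without
rewriting them.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Mapping

from .errors import RowError, SchemaError
from .panel import (
    BackgroundTable,
    Compartment,
    ConcentrationPanel,
    ConcentrationRecord,
    normalize_element,
)

#: Canonical column names of the concentration CSV.
CONCENTRATION_COLUMNS = ("site", "compartment", "element", "replicate", "value_mg_per_g")

_VALID_COMPARTMENTS = {c.value for c in Compartment}


def _resolve(schema: Mapping[str, str] | None, logical: str) -> str:
    return schema.get(logical, logical) if schema else logical


def read_concentrations(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    panel: Iterable[str] | None = None,
) -> ConcentrationPanel:
    """Read a tidy concentration CSV into a :class:`ConcentrationPanel`.

    Parameters
    ----------
    path:
        UTF-8 CSV with (at least) the five canonical columns; decimal point
        is ``.``.
    schema:
        Optional mapping from logical column name (e.g. ``"value_mg_per_g"``)
        to the actual column name in the file.
    panel:
        Optional declared element panel (see :class:`ConcentrationPanel`).

    Raises
    ------
    SchemaError
        If a required column is missing (the message names it).
    RowError
        For a non-numeric/negative value, bad replicate index, or a
        compartment outside ``{soil, biota}`` — with the 1-based line number.
    """
    path = Path(path)
    records: list[ConcentrationRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        cols = {logical: _resolve(schema, logical) for logical in CONCENTRATION_COLUMNS}
        for logical, actual in cols.items():
            if actual not in header:
                raise SchemaError(
                    f"missing required column {actual!r} (for {logical!r}) in {path}"
                )
        for lineno, row in enumerate(reader, start=2):  # header is line 1
            site = (row[cols["site"]] or "").strip()
            comp_raw = (row[cols["compartment"]] or "").strip().lower()
            if comp_raw not in _VALID_COMPARTMENTS:
                raise RowError(
                    f"compartment must be one of {sorted(_VALID_COMPARTMENTS)}, "
                    f"got {row[cols['compartment']]!r}",
                    line=lineno,
                )
            try:
                element = normalize_element(row[cols["element"]])
            except SchemaError as exc:
                raise RowError(str(exc), line=lineno) from exc
            try:
                replicate = int(row[cols["replicate"]])
            except (TypeError, ValueError) as exc:
                raise RowError(
                    f"replicate must be an integer, got {row[cols['replicate']]!r}",
                    line=lineno,
                ) from exc
            raw_value = row[cols["value_mg_per_g"]]
            try:
                value = float(raw_value)
            except (TypeError, ValueError) as exc:
                raise RowError(f"non-numeric value {raw_value!r}", line=lineno) from exc
            if not math.isfinite(value) or value < 0:
                raise RowError(
                    f"concentration must be finite and >= 0, got {raw_value!r}",
                    line=lineno,
                )
            if replicate < 1:
                raise RowError(f"replicate must be >= 1, got {replicate}", line=lineno)
            records.append(
                ConcentrationRecord(site, comp_raw, element, replicate, value)
            )
    if not records:
        raise SchemaError(f"no data rows in {path}")
    return ConcentrationPanel(records, panel=panel)


def write_concentrations(panel: ConcentrationPanel, path: str | Path) -> None:
    """Write a panel back to the canonical tidy CSV.

    Values are written with ``repr(float)`` (shortest round-trip decimal),
    so write → read reproduces every record exactly.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CONCENTRATION_COLUMNS)
        for r in panel:
            writer.writerow(
                [r.site, r.compartment.value, r.element, r.replicate, repr(r.value)]
            )


def read_background(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> BackgroundTable:
    """Read an ``element,background_mg_per_g`` CSV into a :class:`BackgroundTable`."""
    path = Path(path)
    elem_col = _resolve(schema, "element")
    value_col = _resolve(schema, "background_mg_per_g")
    backgrounds: dict[str, float] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in (elem_col, value_col):
            if col not in header:
                raise SchemaError(f"missing required column {col!r} in {path}")
        for lineno, row in enumerate(reader, start=2):
            element = normalize_element(row[elem_col])
            if element in backgrounds:
                raise RowError(f"duplicate background for {element!r}", line=lineno)
            try:
                backgrounds[element] = float(row[value_col])
            except (TypeError, ValueError) as exc:
                raise RowError(
                    f"non-numeric background {row[value_col]!r}", line=lineno
                ) from exc
    if not backgrounds:
        raise SchemaError(f"no data rows in {path}")
    return BackgroundTable(backgrounds)
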