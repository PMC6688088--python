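"""Read exported gating-frequency tables and write population matrices.

Cytometry analysis software exports batch statistics tables in one of two
regional CSV dialects: comma-separated fields with ``.`` decimals (POINT) or
semicolon-separated fields with ``,`` decimals (COMMA).  Both are supported
on read and write; the dialect can be sniffed from the text or forced.

The input table has one row per sample and one column per gating-tree node
(percent of parent), ordered from higher to lower gating levels.  The output
table has one row per sample and one column per combinatorial population
(percent of root), in the canonical enumeration order.
"""

from __future__ import annotations

import enum
import io
import itertools
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd
import yaml

from .compute import GatingTreeValues, NodePath, PopulationVector, node_paths
from .core_model import MarkerState, PanelSpec, combo_name, enumerate_combos
from .errors import (
    DialectError,
    RangeError,
    TableFormatError,
    ValidationError,
)

__all__ = [
    "Dialect",
    "ColumnSchema",
    "SampleRecord",
    "detect_dialect",
    "default_schema",
    "parse_input",
    "write_input_table",
    "write_population_matrix",
    "read_population_matrix",
    "population_frame",
]

#: Fixed output precision (decimal places).  Exceeds the export precision of
#: gating software and makes write -> parse -> write round trips byte-exact.
OUTPUT_DECIMALS = 6

SAMPLE_COLUMN = "Sample"
FREQ_SUFFIX = " | Freq. of Parent"


class Dialect(enum.Enum):
    """CSV dialect: field separator + decimal mark."""

    POINT = ("," , ".")
    COMMA = (";" , ",")

    @property
    def sep(self) -> str:
        return self.value[0]

    @property
    def decimal(self) -> str:
        return self.value[1]

    @classmethod
    def from_name(cls, name: str) -> "Dialect":
        try:
            return cls[name.upper()]
        except KeyError:
            raise ValidationError(
                f"unknown dialect {name!r}; expected 'point' or 'comma'"
            )


def detect_dialect(raw_text: str) -> Dialect:
    """Sniff the CSV dialect from separator and decimal evidence.

    A semicolon anywhere is decisive for COMMA.  Otherwise commas with
    ``.``-decimal numerics (or commas clearly acting as field separators)
    mean POINT.  Text where every comma could equally be a decimal mark, or
    with no separators at all, raises :class:`DialectError` rather than
    guessing; callers can always override explicitly.
    """
    if not raw_text.strip():
        raise DialectError("empty input; cannot detect CSV dialect")
    head = "\n".join(raw_text.splitlines()[:50])
    if ";" in head:
        return Dialect.COMMA
    if "," in head:
        if re.search(r"\d\.\d", head):
            return Dialect.POINT
        # commas but no point-decimals: a comma not flanked by digits on
        # both sides (e.g. between header labels) cannot be a decimal mark,
        # so it is separator evidence
        if re.search(r"(?<!\d),|,(?!\d)", head):
            return Dialect.POINT
        raise DialectError(
            "ambiguous CSV dialect: commas could be separators or decimal "
            "marks; pass the dialect explicitly"
        )
    raise DialectError(
        "no separator or decimal evidence found; pass the dialect explicitly"
    )


def _node_label(path: NodePath, panel: PanelSpec) -> str:
    """Human-readable gate path, e.g. ``CD3+CD4-/CD8+``."""
    parts = []
    for level, child in enumerate(path):
        markers = panel.levels[level]
        bits = [
            (child >> (len(markers) - 1 - k)) & 1
            for k in range(len(markers))
        ]
        parts.append(
            "".join(
                f"{panel.markers[i].name}{'-' if b else '+'}"
                for i, b in zip(markers, bits)
            )
        )
    return "/".join(parts)


def _parse_node_label(label: str, panel: PanelSpec) -> NodePath:
    """Invert :func:`_node_label`; raises on anything malformed."""
    parts = label.split("/")
    if len(parts) > panel.n_levels:
        raise TableFormatError(
            f"gate path {label!r} is deeper than the panel's "
            f"{panel.n_levels} levels"
        )
    path: list[int] = []
    for level, part in enumerate(parts):
        markers = panel.levels[level]
        pattern = "".join(
            re.escape(panel.markers[i].name) + "([+-])" for i in markers
        )
        m = re.fullmatch(pattern, part)
        if m is None:
            raise TableFormatError(
                f"gate segment {part!r} in {label!r} does not match level "
                f"{level} markers {[panel.markers[i].name for i in markers]}"
            )
        child = 0
        for sign in m.groups():
            child = (child << 1) | (1 if sign == "-" else 0)
        path.append(child)
    return tuple(path)


@dataclass
class ColumnSchema:
    """Maps input-table column headers to gating-tree node paths."""

    columns: Dict[str, NodePath]
    sample_column: str = SAMPLE_COLUMN

    def validate(self, panel: PanelSpec) -> None:
        expected = set(node_paths(panel))
        got = set(self.columns.values())
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise TableFormatError(
                "schema does not cover the gating tree exactly once; "
                f"missing paths {missing}, unexpected paths {extra}"
            )

    @classmethod
    def from_file(cls, path, panel: PanelSpec) -> "ColumnSchema":
        """Load an explicit header->gate-path mapping (YAML/JSON).

        The file maps each column header to a gate-path string like
        ``"CD3+CD4-/CD8+"``; an optional ``sample_column`` key overrides
        the sample-id header.
        """
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "columns" not in data:
            raise TableFormatError(
                f"schema file {path} must contain a 'columns' mapping"
            )
        columns = {
            header: _parse_node_label(label, panel)
            for header, label in data["columns"].items()
        }
        schema = cls(columns, data.get("sample_column", SAMPLE_COLUMN))
        schema.validate(panel)
        return schema


def default_schema(panel: PanelSpec) -> ColumnSchema:
    """Canonical schema: one ``<gate-path> | Freq. of Parent`` column per
    tree node, ordered from higher to lower gating levels."""
    columns = {
        _node_label(path, panel) + FREQ_SUFFIX: path
        for path in node_paths(panel)
    }
    return ColumnSchema(columns)


@dataclass
class SampleRecord:
    """One sample's identity, gating tree, and optional group label."""

    sample_id: str
    tree: GatingTreeValues
    group: str | None = None


def parse_input(
    raw_text: str,
    panel: PanelSpec,
    schema: ColumnSchema | None = None,
    dialect: Dialect | None = None,
) -> List[SampleRecord]:
    """Parse an exported frequency table into per-sample gating trees.

    ``schema`` defaults to the canonical header grammar; ``dialect`` is
    sniffed when not given.  Errors name the offending column or cell.
    """
    if dialect is None:
        dialect = detect_dialect(raw_text)
    if schema is None:
        schema = default_schema(panel)
    schema.validate(panel)

    df = pd.read_csv(
        io.StringIO(raw_text),
        sep=dialect.sep,
        decimal=dialect.decimal,
        dtype={0: str},
        skipinitialspace=True,
    )
    df.columns = [str(c).strip() for c in df.columns]

    if schema.sample_column not in df.columns:
        raise TableFormatError(
            f"missing sample-id column {schema.sample_column!r}; "
            f"found columns {list(df.columns)[:5]}..."
        )
    for header in schema.columns:
        if header not in df.columns:
            raise TableFormatError(f"missing input column {header!r}")

    ids = df[schema.sample_column].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise TableFormatError(f"duplicate sample ids: {dupes}")

    records: List[SampleRecord] = []
    for row_pos, (_, row) in enumerate(df.iterrows()):
        tree = GatingTreeValues()
        for header, path in schema.columns.items():
            cell = row[header]
            if pd.isna(cell) or (isinstance(cell, str) and not cell.strip()):
                raise TableFormatError(
                    f"blank cell at row {row_pos + 1} "
                    f"(sample {ids.iloc[row_pos]!r}), column {header!r}"
                )
            try:
                value = float(cell)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"non-numeric value {cell!r} at row {row_pos + 1} "
                    f"(sample {ids.iloc[row_pos]!r}), column {header!r}"
                )
            if not 0.0 <= value <= 100.0:
                raise RangeError(
                    f"value {value} outside [0, 100] at row {row_pos + 1} "
                    f"(sample {ids.iloc[row_pos]!r}), column {header!r}"
                )
            tree[path] = value
        records.append(SampleRecord(ids.iloc[row_pos], tree))
    return records


def _format_number(value: float, dialect: Dialect) -> str:
    text = f"{value:.{OUTPUT_DECIMALS}f}"
    if dialect is Dialect.COMMA:
        text = text.replace(".", ",")
    return text


def _check_id(sample_id: str, dialect: Dialect) -> str:
    if dialect.sep in sample_id or "\n" in sample_id:
        raise ValidationError(
            f"sample id {sample_id!r} contains the field separator"
        )
    return sample_id


def write_input_table(
    records: Sequence[SampleRecord],
    panel: PanelSpec,
    dialect: Dialect = Dialect.POINT,
    schema: ColumnSchema | None = None,
) -> str:
    """Serialize gating trees back to the input-table format (LF, UTF-8)."""
    if schema is None:
        schema = default_schema(panel)
    headers = list(schema.columns)
    lines = [dialect.sep.join([schema.sample_column] + headers)]
    for rec in records:
        cells = [_check_id(rec.sample_id, dialect)]
        for header in headers:
            path = schema.columns[header]
            cells.append(_format_number(rec.tree[path], dialect))
        lines.append(dialect.sep.join(cells))
    return "\n".join(lines) + "\n"


def write_population_matrix(
    records: Sequence[SampleRecord],
    vectors: Sequence[PopulationVector],
    panel: PanelSpec,
    dialect: Dialect = Dialect.POINT,
) -> str:
    """Render the samples x populations matrix as CSV text.

    Header: the sample-id column followed by one column per combination
    name in canonical order; values fixed at 6 decimal places.  The text
    re-parses to values equal at that precision, and a write -> parse ->
    write round trip is byte-identical.
    """
    if len(records) != len(vectors):
        raise ValidationError(
            f"{len(records)} records but {len(vectors)} population vectors"
        )
    combos = enumerate_combos(panel)
    names = [combo_name(c, panel) for c in combos]
    lines = [dialect.sep.join([SAMPLE_COLUMN] + names)]
    for rec, vec in zip(records, vectors):
        if len(vec) != len(combos):
            raise ValidationError(
                f"population vector for sample {rec.sample_id!r} has "
                f"{len(vec)} entries, expected {len(combos)}"
            )
        cells = [_check_id(rec.sample_id, dialect)]
        cells += [_format_number(vec[c], dialect) for c in combos]
        lines.append(dialect.sep.join(cells))
    return "\n".join(lines) + "\n"


def population_frame(
    records: Sequence[SampleRecord],
    vectors: Sequence[PopulationVector],
    panel: PanelSpec,
) -> pd.DataFrame:
    """Samples x populations DataFrame, columns named in canonical order."""
    if len(records) != len(vectors):
        raise ValidationError(
            f"{len(records)} records but {len(vectors)} population vectors"
        )
    combos = enumerate_combos(panel)
    return pd.DataFrame(
        [[vec[c] for c in combos] for vec in vectors],
        index=pd.Index([r.sample_id for r in records], name=SAMPLE_COLUMN),
        columns=[combo_name(c, panel) for c in combos],
    )


def read_population_matrix(
    raw_text: str, dialect: Dialect | None = None
) -> pd.DataFrame:
    """Parse a population matrix CSV into a DataFrame indexed by sample id."""
    if dialect is None:
        dialect = detect_dialect(raw_text)
    df = pd.read_csv(
        io.StringIO(raw_text),
        sep=dialect.sep,
        decimal=dialect.decimal,
        index_col=0,
        dtype={0: str},
    )
    df.index = df.index.astype(str)
    df.index.name = SAMPLE_COLUMN
    return df.astype(float)
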