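"""The upload workflow: template sheets as CSV.

Mirrors a spreadsheet wizard without a GUI: from a declared brick schema
the system emits a CSV *template sheet* whose header cells carry every
variable name and unit; the user pastes dimension-variable values and
data into the labeled cells; the filled sheet is parsed back, each cell
validated (with upload-template policies applied), and the resulting
brick registered together with a user-supplied process record.

Layout (RFC 4180 CSV, UTF-8).  ``#``-prefixed rows are metadata::

    #name,<brick name>
    #data_category,<CURIE>
    #dim,<axis>,<dim type CURIE>,<size>
    #var,<axis>,<microtype CURIE>,<unit CURIE or empty>   (per variable)
    #value_set,<microtype CURIE>,<unit CURIE or empty>    (per value set)

1-D schemas are a plain table: one header row of variable labels then
value-set labels, one row per coordinate.  For >=2-D schemas, variables
of axes 2.. are given in ``#dim_values,<axis>`` sections, and each value
set is written as one labeled 2-D slab per trailing coordinate
(``#slab,<set>,<i2>,...``): axis-1 variable labels and values across the
top, axis-0 variables down the left, data in the body.  Blank data cells
are nulls (warned).  The labeled layout is part of the contract: a sheet
whose label cells disagree with its schema is rejected.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .bricks import (
    DataBrick,
    DimensionSpec,
    ValidationReport,
    build_brick,
)
from .contextons import make_contexton
from .errors import PolicyViolation, SheetError
from .instance import Instance
from .microtypes import Microtype, ScalarKind
from .ontology import Term
from .templates import BrickDraft, UploadTemplate, apply_upload_template, enforce_policy

__all__ = [
    "DimSchema",
    "SheetSchema",
    "generate_template_sheet",
    "render_sheet",
    "parse_filled_sheet",
    "rows_to_csv",
    "csv_to_rows",
]


@dataclass(frozen=True)
class DimSchema:
    dim_type: Term
    size: int
    variables: tuple[tuple[Microtype, Term | None], ...]


@dataclass(frozen=True)
class SheetSchema:
    """The declared structure a sheet is generated from and parsed
    against: dimensions (with sizes and variable microtypes/units) and
    value sets."""

    name: str
    data_category: Term
    dims: tuple[DimSchema, ...]
    value_sets: tuple[tuple[Microtype, Term | None], ...]

    @classmethod
    def from_brick(cls, brick: DataBrick) -> "SheetSchema":
        return cls(
            name=brick.name,
            data_category=brick.data_category,
            dims=tuple(
                DimSchema(
                    d.dim_type,
                    d.size,
                    tuple((v.microtype, v.unit) for v in d.variables),
                )
                for d in brick.dims
            ),
            value_sets=tuple(
                (vs.microtype, vs.unit) for vs in brick.value_sets
            ),
        )

    def to_doc(self) -> dict:
        return {
            "name": self.name,
            "data_category": self.data_category.id,
            "dims": [
                {
                    "dim_type": d.dim_type.id,
                    "size": d.size,
                    "variables": [
                        {"microtype": m.id, "unit": u.id if u else None}
                        for m, u in d.variables
                    ],
                }
                for d in self.dims
            ],
            "value_sets": [
                {"microtype": m.id, "unit": u.id if u else None}
                for m, u in self.value_sets
            ],
        }

    @classmethod
    def from_doc(cls, doc: Mapping, instance: Instance) -> "SheetSchema":
        reg, idx = instance.microtypes, instance.terms

        def pair(d):
            return (
                reg.get(d["microtype"]),
                idx.get(d["unit"]) if d.get("unit") else None,
            )

        return cls(
            name=doc["name"],
            data_category=idx.resolve(doc["data_category"]),
            dims=tuple(
                DimSchema(
                    idx.resolve(d["dim_type"]),
                    int(d["size"]),
                    tuple(pair(v) for v in d["variables"]),
                )
                for d in doc["dims"]
            ),
            value_sets=tuple(pair(v) for v in doc["value_sets"]),
        )


def _label(mt: Microtype, unit: Term | None) -> str:
    return f"{mt.name} ({unit.label})" if unit is not None else mt.name


def _format(v: Any) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, Term):
        return v.id
    return str(v)


def _parse_cell(text: str, mt: Microtype, instance: Instance) -> Any:
    text = text.strip()
    if text == "":
        return None
    kind = mt.scalar_type
    try:
        if kind == ScalarKind.INT:
            return int(text)
        if kind == ScalarKind.FLOAT:
            return float(text)
        if kind == ScalarKind.BOOLEAN:
            if text.lower() in ("true", "1", "yes"):
                return True
            if text.lower() in ("false", "0", "no"):
                return False
            raise ValueError(text)
        if kind == ScalarKind.OTERM_REF:
            return instance.terms.resolve(text).id
    except ValueError:
        return text  # type mismatch surfaces as a validation reason code
    except Exception:
        return text
    return text


def render_sheet(
    schema: SheetSchema,
    dim_values: Sequence[Sequence[Sequence[Any]]] | None = None,
    values: Sequence[np.ndarray] | None = None,
) -> list[list[str]]:
    """Rows of the sheet; with ``dim_values``/``values`` omitted the data
    region is left blank (the empty template)."""
    ndim = len(schema.dims)
    if ndim == 0:
        raise SheetError("sheets require at least one dimension")

    def dv(axis: int, var: int, i: int) -> str:
        if dim_values is None:
            return ""
        return _format(dim_values[axis][var][i])

    def val(k: int, coord: tuple) -> str:
        if values is None:
            return ""
        return _format(values[k][coord])

    rows: list[list[str]] = [
        ["#name", schema.name],
        ["#data_category", schema.data_category.id],
    ]
    for a, d in enumerate(schema.dims):
        rows.append(["#dim", str(a), d.dim_type.id, str(d.size)])
        for m, u in d.variables:
            rows.append(["#var", str(a), m.id, u.id if u else ""])
    for m, u in schema.value_sets:
        rows.append(["#value_set", m.id, u.id if u else ""])

    if ndim == 1:
        d0 = schema.dims[0]
        header = [_label(m, u) for m, u in d0.variables] + [
            _label(m, u) for m, u in schema.value_sets
        ]
        rows.append(header)
        for i in range(d0.size):
            row = [dv(0, j, i) for j in range(len(d0.variables))]
            row += [val(k, (i,)) for k in range(len(schema.value_sets))]
            rows.append(row)
        return rows

    # trailing-axis variable sections
    for a in range(2, ndim):
        rows.append(["#dim_values", str(a)])
        d = schema.dims[a]
        for j, (m, u) in enumerate(d.variables):
            rows.append(
                [_label(m, u)] + [dv(a, j, i) for i in range(d.size)]
            )

    d0, d1 = schema.dims[0], schema.dims[1]
    R, C = len(d0.variables), len(d1.variables)
    trailing = tuple(d.size for d in schema.dims[2:])
    for k in range(len(schema.value_sets)):
        for tcoord in np.ndindex(trailing) if trailing else [()]:
            rows.append(["#slab", str(k)] + [str(c) for c in tcoord])
            for j1, (m, u) in enumerate(d1.variables):
                row = [""] * (R - 1) + [_label(m, u)]
                row += [dv(1, j1, c) for c in range(d1.size)]
                rows.append(row)
            corner = [_label(m, u) for m, u in d0.variables] + [""] * d1.size
            rows.append(corner)
            for r in range(d0.size):
                row = [dv(0, j, r) for j in range(R)]
                row += [
                    val(k, (r, c) + tcoord) for c in range(d1.size)
                ]
                rows.append(row)
    return rows


def generate_template_sheet(schema: SheetSchema) -> list[list[str]]:
    """The empty labeled template for a schema (data region blank)."""
    return render_sheet(schema)


def rows_to_csv(rows: Sequence[Sequence[str]]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerows(rows)
    return buf.getvalue()


def csv_to_rows(text: str) -> list[list[str]]:
    return [row for row in csv.reader(io.StringIO(text))]


def _schema_from_rows(rows, instance: Instance) -> tuple[SheetSchema, int]:
    """Reconstruct the schema from metadata rows; returns (schema, index
    of the first non-metadata/metadata-section row)."""
    name = None
    category = None
    dims: list[tuple[Term, int, list]] = []
    value_sets: list[tuple[Microtype, Term | None]] = []
    i = 0
    for i, row in enumerate(rows):
        head = row[0] if row else ""
        if head == "#name":
            name = row[1]
        elif head == "#data_category":
            category = instance.terms.resolve(row[1])
        elif head == "#dim":
            dims.append((instance.terms.resolve(row[2]), int(row[3]), []))
        elif head == "#var":
            axis = int(row[1])
            if axis >= len(dims):
                raise SheetError(f"#var row for undeclared dimension {axis}")
            unit = instance.terms.get(row[3]) if row[3] else None
            dims[axis][2].append((instance.microtypes.get(row[2]), unit))
        elif head == "#value_set":
            unit = instance.terms.get(row[2]) if row[2] else None
            value_sets.append((instance.microtypes.get(row[1]), unit))
        else:
            break
    else:
        i = len(rows)
    if name is None or category is None:
        raise SheetError("sheet lacks #name/#data_category metadata")
    if not dims or not value_sets:
        raise SheetError("sheet lacks dimension or value-set metadata")
    schema = SheetSchema(
        name=name,
        data_category=category,
        dims=tuple(DimSchema(t, n, tuple(vs)) for t, n, vs in dims),
        value_sets=tuple(value_sets),
    )
    return schema, i


def parse_filled_sheet(
    rows: Sequence[Sequence[str]],
    instance: Instance,
    schema: SheetSchema | None = None,
    upload_template: UploadTemplate | None = None,
) -> tuple[DataBrick | None, ValidationReport]:
    """Parse a filled template back into an (unsaved) brick.

    Cell values are typed by their microtype; blank cells become nulls
    (warned); upload-template policies are applied per cell via
    :func:`~brickstore.templates.enforce_policy`.  Layout/label mismatch
    against the (embedded or supplied) schema is an error.  The returned
    brick is ``None`` whenever the report carries errors; registration —
    with the user-supplied process record — is the caller's final step.
    """
    report = ValidationReport()
    found, body_start = _schema_from_rows(rows, instance)
    if schema is not None and found.to_doc() != schema.to_doc():
        raise SheetError("sheet metadata does not match the expected schema")
    schema = found

    draft = BrickDraft(name=schema.name, data_category=schema.data_category)
    if upload_template is not None:
        draft = apply_upload_template(upload_template, draft)

    def policy_cell(mt: Microtype, unit, raw: str, where: str):
        v = _parse_cell(raw, mt, instance)
        if v is None and raw.strip() == "":
            report.warn(f"{where}: blank cell treated as null")
            return None
        try:
            v2, warning = enforce_policy(
                mt,
                v,
                unit,
                draft.policy_for(mt),
                ontologies=instance.terms,
                extra_validator=draft.validator_for(mt),
            )
        except PolicyViolation as e:
            report.add(where, "policy-error", str(e))
            return None
        if warning:
            report.warn(f"{where}: {warning}")
        return v2

    ndim = len(schema.dims)
    dim_values = [
        [[None] * d.size for _ in d.variables] for d in schema.dims
    ]
    value_arrays = [
        np.full(tuple(d.size for d in schema.dims), None, dtype=object)
        for _ in schema.value_sets
    ]
    body = [list(r) for r in rows[body_start:]]

    def expect_label(cell: str, mt: Microtype, unit, where: str):
        if cell != _label(mt, unit):
            raise SheetError(
                f"{where}: header label {cell!r} does not match schema "
                f"({_label(mt, unit)!r}); the labeled layout is bit-exact"
            )

    if ndim == 1:
        d0 = schema.dims[0]
        if not body:
            raise SheetError("missing header row")
        header = body[0]
        expected = [_label(m, u) for m, u in d0.variables] + [
            _label(m, u) for m, u in schema.value_sets
        ]
        if header[: len(expected)] != expected:
            raise SheetError(
                f"header row {header!r} does not match schema {expected!r}"
            )
        data_rows = body[1 : 1 + d0.size]
        if len(data_rows) != d0.size:
            raise SheetError(
                f"expected {d0.size} data rows, found {len(data_rows)}"
            )
        for i, row in enumerate(data_rows):
            row = row + [""] * (len(expected) - len(row))
            for j, (m, u) in enumerate(d0.variables):
                dim_values[0][j][i] = policy_cell(m, u, row[j], f"row {i} var {j}")
            for k, (m, u) in enumerate(schema.value_sets):
                value_arrays[k][(i,)] = policy_cell(
                    m, u, row[len(d0.variables) + k], f"row {i} value {k}"
                )
    else:
        d0, d1 = schema.dims[0], schema.dims[1]
        R = len(d0.variables)
        pos = 0
        # trailing-axis variable sections
        for a in range(2, ndim):
            if pos >= len(body) or body[pos][:2] != ["#dim_values", str(a)]:
                raise SheetError(f"expected #dim_values section for axis {a}")
            pos += 1
            d = schema.dims[a]
            for j, (m, u) in enumerate(d.variables):
                row = body[pos]
                pos += 1
                expect_label(row[0], m, u, f"axis {a} var {j}")
                cells = row[1 : 1 + d.size]
                if len(cells) != d.size:
                    raise SheetError(f"axis {a} var {j}: wrong length")
                for i, cell in enumerate(cells):
                    dim_values[a][j][i] = policy_cell(
                        m, u, cell, f"axis {a} var {j} [{i}]"
                    )
        trailing = tuple(d.size for d in schema.dims[2:])
        first_slab = True
        for k in range(len(schema.value_sets)):
            for tcoord in np.ndindex(trailing) if trailing else [()]:
                want = ["#slab", str(k)] + [str(c) for c in tcoord]
                if pos >= len(body) or body[pos][: len(want)] != want:
                    raise SheetError(f"expected slab header {want}")
                pos += 1
                for j1, (m, u) in enumerate(d1.variables):
                    row = body[pos]
                    pos += 1
                    expect_label(row[R - 1], m, u, f"slab {want} col-var {j1}")
                    cells = row[R : R + d1.size]
                    if len(cells) != d1.size:
                        raise SheetError(f"col-var {j1}: wrong length")
                    for c, cell in enumerate(cells):
                        v = policy_cell(m, u, cell, f"col-var {j1} [{c}]")
                        if first_slab:
                            dim_values[1][j1][c] = v
                corner = body[pos]
                pos += 1
                for j, (m, u) in enumerate(d0.variables):
                    expect_label(corner[j], m, u, f"slab {want} row-var {j}")
                for r in range(d0.size):
                    row = body[pos]
                    pos += 1
                    row = row + [""] * (R + d1.size - len(row))
                    for j, (m, u) in enumerate(d0.variables):
                        v = policy_cell(m, u, row[j], f"row-var {j} [{r}]")
                        if first_slab:
                            dim_values[0][j][r] = v
                    for c in range(d1.size):
                        value_arrays[k][(r, c) + tcoord] = policy_cell(
                            *schema.value_sets[k],
                            row[R + c],
                            f"value {k} {(r, c) + tcoord}",
                        )
                first_slab = False

    if not report.ok:
        return None, report

    try:
        dims = tuple(
            DimensionSpec(
                dim_type=d.dim_type,
                size=d.size,
                variables=tuple(
                    make_contexton(m, dim_values[a][j], unit=u, ontologies=instance.terms)
                    for j, (m, u) in enumerate(d.variables)
                ),
            )
            for a, d in enumerate(schema.dims)
        )
        value_sets = tuple(
            make_contexton(m, value_arrays[k], unit=u, ontologies=instance.terms)
            for k, (m, u) in enumerate(schema.value_sets)
        )
        brick = build_brick(
            schema.name,
            schema.data_category,
            dims,
            value_sets,
            system=instance.require_system(),
            registry=instance.microtypes,
        )
    except Exception as e:  # aggregate rather than raise: report is total
        report.add("brick", "build-failure", str(e))
        return None, report
    return brick, report
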