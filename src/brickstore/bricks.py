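"""Data bricks: N-dimensional datasets whose every part carries context.

A brick is the instance of a dynamic type: an ordered list of dimensions
(each with a *Dimension Type* term and one or more 1-D variable
contextons), one or more N-D value sets (homogeneous arrays, each with
its own microtype and unit), scalar overall-context contextons, and a
mandatory *Data Category* term and *Brick Name*.  A permanent Brick ID is
assigned only when the brick is registered in a provenance store.

Every manipulation (slice, aggregate, join) is pure — it returns a new
brick and appends exactly one record to the brick's *session provenance*,
so any derived brick can be reproduced from its origin by
:func:`replay_session`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np

from .contextons import Contexton, make_contexton
from .errors import BrickError, MicrotypeError
from .microtypes import (
    Microtype,
    MicrotypeRegistry,
    ScalarKind,
    SystemMicrotypes,
    NUMERIC_KINDS,
)
from .ontology import Term

__all__ = [
    "DimensionSpec",
    "DataBrick",
    "SessionProvenance",
    "ValidationFinding",
    "ValidationReport",
    "build_brick",
    "validate_brick",
    "enumerate_points",
    "PointRecord",
    "slice_brick",
    "aggregate_dimension",
    "replay_session",
    "serialize_brick",
    "deserialize_brick",
    "OPS",
]

FORMAT_VERSION = 1

AGG_STATS = ("mean", "sum", "min", "max")


@dataclass(frozen=True)
class DimensionSpec:
    """One brick dimension: what varies along the axis and how long it is."""

    dim_type: Term
    size: int
    variables: tuple[Contexton, ...]

    def __post_init__(self):
        if self.size <= 0:
            raise BrickError(f"dimension size must be positive, got {self.size}")
        if not self.variables:
            raise BrickError("each dimension must carry at least one contexton")

    def informative(self) -> bool:
        return any(not v.microtype.non_informative for v in self.variables)

    def var_labels(self) -> list[str]:
        return [v.label for v in self.variables]


@dataclass(frozen=True)
class SessionProvenance:
    """Replayable record of all manipulations since retrieval."""

    origin_brick_id: str | None = None
    ops: tuple[tuple[str, dict], ...] = ()

    def append(self, name: str, params: dict) -> "SessionProvenance":
        return SessionProvenance(self.origin_brick_id, self.ops + ((name, params),))

    def to_doc(self) -> dict:
        return {
            "origin_brick_id": self.origin_brick_id,
            "ops": [[name, params] for name, params in self.ops],
        }

    @classmethod
    def from_doc(cls, doc: Mapping) -> "SessionProvenance":
        return cls(
            origin_brick_id=doc.get("origin_brick_id"),
            ops=tuple((name, dict(params)) for name, params in doc.get("ops", ())),
        )

    def __eq__(self, other):
        if not isinstance(other, SessionProvenance):
            return NotImplemented
        # compare through the serialized form so replay is insensitive to
        # int/list vs tuple differences introduced by round trips
        return json.loads(json.dumps(self.to_doc())) == json.loads(
            json.dumps(other.to_doc())
        )

    def __hash__(self):
        return hash(json.dumps(self.to_doc(), sort_keys=True))


@dataclass(frozen=True)
class DataBrick:
    """See module docstring.  Equality ignores ``brick_id`` (a replayed
    brick is equal to the stored derived brick it reproduces)."""

    name: str
    data_category: Term
    dims: tuple[DimensionSpec, ...]
    value_sets: tuple[Contexton, ...]
    overall_context: tuple[Contexton, ...] = ()
    session: SessionProvenance = field(default_factory=SessionProvenance)
    brick_id: str | None = None

    @property
    def shape(self) -> list[int]:
        return [d.size for d in self.dims]

    @property
    def ndim(self) -> int:
        return len(self.dims)

    def value_set(self, query: str) -> Contexton:
        for vs in self.value_sets:
            if query in (vs.microtype.name, vs.microtype.id):
                return vs
        raise BrickError(f"no value set {query!r} in brick {self.name!r}")

    def with_session(self, name: str, params: dict) -> "SessionProvenance":
        sess = self.session
        if sess.origin_brick_id is None and self.brick_id is not None and not sess.ops:
            # first manipulation of a freshly retrieved brick: root the
            # session at its permanent id so it can be replayed
            sess = SessionProvenance(origin_brick_id=self.brick_id)
        return sess.append(name, params)

    def __eq__(self, other):
        if not isinstance(other, DataBrick):
            return NotImplemented
        return (
            self.name == other.name
            and self.data_category.id == other.data_category.id
            and len(self.dims) == len(other.dims)
            and all(
                a.dim_type.id == b.dim_type.id
                and a.size == b.size
                and a.variables == b.variables
                for a, b in zip(self.dims, other.dims)
            )
            and self.value_sets == other.value_sets
            and sorted(self.overall_context, key=lambda c: c.microtype.id)
            == sorted(other.overall_context, key=lambda c: c.microtype.id)
            and self.session == other.session
        )

    def __hash__(self):
        return hash((self.name, self.data_category.id, tuple(self.shape)))


@dataclass(frozen=True)
class ValidationFinding:
    path: str
    code: str
    detail: str = ""


class ValidationReport:
    """Accumulated findings; ``ok`` iff empty."""

    def __init__(self, findings: Iterable[ValidationFinding] = ()):
        self.findings: list[ValidationFinding] = list(findings)
        self.warnings: list[str] = []  # non-fatal notes (policy adjustments)

    @property
    def ok(self) -> bool:
        return not self.findings

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def add(self, path: str, code: str, detail: str = "") -> None:
        self.findings.append(ValidationFinding(path, code, detail))

    def extend(self, other: "ValidationReport") -> None:
        self.findings.extend(other.findings)

    def __iter__(self):
        return iter(self.findings)

    def __len__(self):
        return len(self.findings)

    def __repr__(self):
        if self.ok:
            return "<ValidationReport ok>"
        lines = [f"  {f.path}: {f.code} {f.detail}".rstrip() for f in self.findings]
        return "<ValidationReport {} finding(s)\n{}\n>".format(
            len(self.findings), "\n".join(lines)
        )


def build_brick(
    name: str,
    data_category: Term | str,
    dims: Sequence[DimensionSpec],
    value_sets: Sequence[Contexton],
    overall_context: Sequence[Contexton] = (),
    *,
    system: SystemMicrotypes,
    registry: MicrotypeRegistry,
) -> DataBrick:
    """Construct and fully validate an (unsaved) brick.

    ``data_category`` and each dimension's ``dim_type`` must be among the
    ontological terms allowed by the instance's system microtypes.
    """
    index = registry.term_index
    if isinstance(data_category, str):
        data_category = index.resolve(data_category)
    if not name:
        raise BrickError("brick name is mandatory")
    allowed_cat = {t.id for t in system.allowed_terms("data_category", index)}
    if data_category.id not in allowed_cat:
        raise BrickError(
            f"data category {data_category.label!r} is not among the allowed "
            "Data Category terms of this instance"
        )
    allowed_dim = {t.id for t in system.allowed_terms("dimension_type", index)}
    for i, d in enumerate(dims):
        if d.dim_type.id not in allowed_dim:
            raise BrickError(
                f"dimension {i}: type {d.dim_type.label!r} is not an allowed "
                "Dimension Type term"
            )
    if not value_sets:
        raise BrickError("a brick requires at least one value set")

    brick = DataBrick(
        name=name,
        data_category=data_category,
        dims=tuple(dims),
        value_sets=tuple(value_sets),
        overall_context=tuple(overall_context),
    )
    report = validate_brick(brick, registry)
    if not report.ok:
        raise BrickError(f"invalid brick {name!r}: {report!r}")
    return brick


def validate_brick(
    brick: DataBrick,
    registry: MicrotypeRegistry,
    store=None,
) -> ValidationReport:
    """Exhaustive structural + self-validation check; total function.

    With a ``store``, additionally verifies that every object_ref value in
    dimension variables and value sets resolves to a live object of the
    target core type (presence of all linked datasets).
    """
    rep = ValidationReport()
    index = registry.term_index

    if not brick.name:
        rep.add("name", "missing-brick-name")
    if brick.data_category is None:
        rep.add("data_category", "missing-data-category")
    if not brick.value_sets:
        rep.add("value_sets", "empty-value-sets")

    shape = brick.shape
    for i, d in enumerate(brick.dims):
        if not d.informative():
            rep.add(
                f"dims[{i}]",
                "all-comment-dimension",
                "every variable has a non-informative microtype",
            )
        for j, v in enumerate(d.variables):
            path = f"dims[{i}].variables[{j}]"
            if v.shape != [d.size]:
                rep.add(path, "shape-mismatch", f"{v.shape} != [{d.size}]")
            if not v.is_scalar and v.values.ndim != 1:
                rep.add(path, "dimension-variable-not-1d")
            for coord, res in v.revalidate(index):
                rep.add(f"{path}[{coord}]", *_res_detail(res))
            _check_refs(v, store, path, rep)

    for k, vs in enumerate(brick.value_sets):
        path = f"value_sets[{k}]"
        if vs.shape != shape:
            rep.add(path, "shape-mismatch", f"{vs.shape} != {shape}")
        for coord, res in vs.revalidate(index):
            rep.add(f"{path}[{coord}]", *_res_detail(res))
        _check_refs(vs, store, path, rep)

    for k, c in enumerate(brick.overall_context):
        path = f"overall_context[{k}]"
        if not c.is_scalar:
            rep.add(path, "overall-context-not-scalar")
        for coord, res in c.revalidate(index):
            rep.add(f"{path}[{coord}]", *_res_detail(res))
        _check_refs(c, store, path, rep)

    return rep


def _res_detail(res) -> tuple[str, str]:
    return ("self-validation", ",".join(res.reasons))


def _check_refs(contexton: Contexton, store, path: str, rep: ValidationReport) -> None:
    if store is None or contexton.microtype.scalar_type != ScalarKind.OBJECT_REF:
        return
    target = contexton.microtype.ref_target
    for coord, v in contexton.iter_values():
        if v is None:
            continue
        if store.resolve_pk(target, v) is None:
            rep.add(
                f"{path}[{coord}]",
                "dangling-reference",
                f"no live {target} named {v!r}",
            )


# ---------------------------------------------------------------------------
# flattened view


@dataclass(frozen=True)
class PointRecord:
    """One (context assignment, value) pair of the flattened brick.

    ``context`` maps a variable key — (microtype CURIE, unit CURIE or
    None, canonical modifier tuple) — to the value of that variable at
    this coordinate.  Overall-context contextons appear with the same key
    shape.  Used by search, joins, and representation-equivalence checks.
    """

    context: tuple[tuple[tuple, Any], ...]
    value_microtype: str
    value_unit: str | None
    value: Any
    is_null: bool

    def key(self):
        return (
            frozenset(self.context),
            self.value_microtype,
            self.value_unit,
            self.value,
            self.is_null,
        )


def _ctx_key(c: Contexton) -> tuple:
    mods = tuple(
        sorted(
            (m.microtype.id, m.unit.id if m.unit else None, m.scalar_value())
            for m in c.modifiers
        )
    )
    return (c.microtype.id, c.unit.id if c.unit else None, mods)


def enumerate_points(brick: DataBrick) -> list[PointRecord]:
    """Flatten to (prod(sizes) x len(value_sets)) records, nulls included."""
    overall = tuple((_ctx_key(c), c.scalar_value()) for c in brick.overall_context)
    shape = tuple(brick.shape)
    out: list[PointRecord] = []
    for coord in np.ndindex(shape):
        ctx = list(overall)
        for axis, d in enumerate(brick.dims):
            i = coord[axis]
            for v in d.variables:
                ctx.append((_ctx_key(v), v.value_at((i,))))
        ctx_t = tuple(ctx)
        for vs in brick.value_sets:
            out.append(
                PointRecord(
                    context=ctx_t,
                    value_microtype=vs.microtype.id,
                    value_unit=vs.unit.id if vs.unit else None,
                    value=vs.value_at(coord),
                    is_null=bool(vs.mask[coord]),
                )
            )
    return out


def point_multiset(brick: DataBrick):
    """Multiset (Counter) of canonical point keys, for equivalence tests."""
    from collections import Counter

    return Counter(r.key() for r in enumerate_points(brick))


# ---------------------------------------------------------------------------
# manipulations (pure; each appends one session record)


def _take(c: Contexton, indices: np.ndarray, axis: int) -> Contexton:
    return Contexton(
        microtype=c.microtype,
        values=np.take(c.values, indices, axis=axis),
        mask=np.take(c.mask, indices, axis=axis),
        unit=c.unit,
        modifiers=c.modifiers,
    )


def _resolve_selector(brick: DataBrick, dim: int, selector) -> list[int]:
    d = brick.dims[dim]
    if callable(selector):
        indices = []
        for i in range(d.size):
            row = {v.microtype.name: v.value_at((i,)) for v in d.variables}
            if selector(row):
                indices.append(i)
    else:
        indices = [int(i) for i in selector]
    for i in indices:
        if not (0 <= i < d.size):
            raise BrickError(f"index {i} out of range for dimension {dim}")
    if not indices:
        raise BrickError("empty selection")
    return indices


def slice_brick(brick: DataBrick, dim: int, selector) -> DataBrick:
    """Restrict one dimension to selected coordinates.

    ``selector`` is a list of integer indices or a predicate over a dict
    of the dimension's variable values at each coordinate.  Predicates are
    resolved to explicit indices before being recorded in the session, so
    replay does not depend on the predicate object.
    """
    if not (0 <= dim < brick.ndim):
        raise BrickError(f"no dimension {dim} in a {brick.ndim}-D brick")
    indices = _resolve_selector(brick, dim, selector)
    idx = np.asarray(indices)
    d = brick.dims[dim]
    new_dim = DimensionSpec(
        dim_type=d.dim_type,
        size=len(indices),
        variables=tuple(_take(v, idx, 0) for v in d.variables),
    )
    dims = brick.dims[:dim] + (new_dim,) + brick.dims[dim + 1 :]
    value_sets = tuple(_take(vs, idx, dim) for vs in brick.value_sets)
    return DataBrick(
        name=brick.name,
        data_category=brick.data_category,
        dims=dims,
        value_sets=value_sets,
        overall_context=brick.overall_context,
        session=brick.with_session("slice", {"dim": dim, "indices": list(indices)}),
    )


def _masked_reduce(values: np.ndarray, mask: np.ndarray, axis: int, stat: str):
    valid = ~mask
    cnt = valid.sum(axis=axis)
    all_null = cnt == 0
    if stat == "sum":
        filled = np.where(mask, 0, values)
        out = filled.sum(axis=axis)
    elif stat == "mean":
        filled = np.where(mask, 0.0, values.astype(np.float64))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = filled.sum(axis=axis) / np.maximum(cnt, 1)
        out = out.astype(np.float64)
    else:  # min / max
        ma = np.ma.array(values, mask=mask)
        red = ma.min(axis=axis) if stat == "min" else ma.max(axis=axis)
        out = np.ma.filled(red, 0)
    out = np.asarray(out)
    if stat == "sum":
        out = np.where(all_null, 0, out)
    return out, all_null


def aggregate_dimension(brick: DataBrick, dim: int, statistic: str) -> DataBrick:
    """Remove a dimension by reducing every value set over it.

    Nulls are ignored; cells whose every contributing value is null become
    null.  ``mean`` yields floats and is therefore refused on integer
    value sets; ``sum``/``min``/``max`` preserve the scalar type.
    """
    if statistic not in AGG_STATS:
        raise BrickError(f"unknown statistic {statistic!r}; use one of {AGG_STATS}")
    if not (0 <= dim < brick.ndim):
        raise BrickError(f"no dimension {dim} in a {brick.ndim}-D brick")
    for vs in brick.value_sets:
        if vs.microtype.scalar_type not in NUMERIC_KINDS:
            raise BrickError(
                f"value set {vs.microtype.name!r} is not numeric; cannot aggregate"
            )
        if statistic == "mean" and vs.microtype.scalar_type == ScalarKind.INT:
            raise BrickError(
                f"mean of integer value set {vs.microtype.name!r} is not "
                "representable in its scalar type; use sum/min/max"
            )
    new_sets = []
    for vs in brick.value_sets:
        out, null = _masked_reduce(vs.values, vs.mask, dim, statistic)
        arr = np.asarray(out)
        if vs.microtype.scalar_type == ScalarKind.FLOAT:
            arr = arr.astype(np.float64)
            arr = np.where(null, np.nan, arr)
        arr = np.asarray(arr)
        arr.setflags(write=False)
        nmask = np.asarray(null, dtype=bool)
        nmask.setflags(write=False)
        new_sets.append(
            Contexton(
                microtype=vs.microtype,
                values=arr,
                mask=nmask,
                unit=vs.unit,
                modifiers=vs.modifiers,
            )
        )
    dims = brick.dims[:dim] + brick.dims[dim + 1 :]
    return DataBrick(
        name=brick.name,
        data_category=brick.data_category,
        dims=dims,
        value_sets=tuple(new_sets),
        overall_context=brick.overall_context,
        session=brick.with_session(
            "aggregate", {"dim": dim, "statistic": statistic}
        ),
    )


# registered session operations: name -> fn(store, brick, params) -> brick
OPS: dict[str, Callable] = {
    "slice": lambda store, b, p: slice_brick(b, p["dim"], p["indices"]),
    "aggregate": lambda store, b, p: aggregate_dimension(b, p["dim"], p["statistic"]),
}


def replay_session(store, session: SessionProvenance) -> DataBrick:
    """Re-execute a session's ops on its origin brick.

    All ops are deterministic, so the result equals the stored derived
    brick bit-for-bit (floats IEEE-exact).
    """
    if session.origin_brick_id is None:
        raise BrickError("session has no origin brick")
    brick = store.get(session.origin_brick_id)
    if not session.ops:
        return brick  # identity session

    # a freshly retrieved brick starts a new session rooted at its id
    brick = replace(
        brick, session=SessionProvenance(origin_brick_id=session.origin_brick_id)
    )
    for name, params in session.ops:
        if name not in OPS:
            raise BrickError(f"unknown session op {name!r}")
        brick = OPS[name](store, brick, params)
    return brick


# ---------------------------------------------------------------------------
# serialization (canonical JSON dialect; NetCDF-4 codec in .netcdf)


def serialize_brick(brick: DataBrick) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "kind": "brick",
        "id": brick.brick_id,
        "name": brick.name,
        "data_category": brick.data_category.id,
        "dims": [
            {
                "dim_type": d.dim_type.id,
                "size": d.size,
                "variables": [v.to_doc() for v in d.variables],
            }
            for d in brick.dims
        ],
        "value_sets": [vs.to_doc() for vs in brick.value_sets],
        "overall_context": [c.to_doc() for c in brick.overall_context],
        "session": brick.session.to_doc(),
    }


def deserialize_brick(doc: Mapping, registry: MicrotypeRegistry) -> DataBrick:
    if doc.get("kind") != "brick":
        raise BrickError("not a brick document")
    if doc.get("format_version") != FORMAT_VERSION:
        raise BrickError(f"unsupported format_version {doc.get('format_version')!r}")
    if not doc.get("name"):
        raise BrickError("brick document lacks the mandatory Brick Name")
    if not doc.get("data_category"):
        raise BrickError("brick document lacks the mandatory Data Category")
    index = registry.term_index
    dims = tuple(
        DimensionSpec(
            dim_type=index.get(d["dim_type"]),
            size=int(d["size"]),
            variables=tuple(
                Contexton.from_doc(v, registry) for v in d["variables"]
            ),
        )
        for d in doc["dims"]
    )
    brick = DataBrick(
        name=doc["name"],
        data_category=index.get(doc["data_category"]),
        dims=dims,
        value_sets=tuple(
            Contexton.from_doc(v, registry) for v in doc["value_sets"]
        ),
        overall_context=tuple(
            Contexton.from_doc(c, registry) for c in doc.get("overall_context", ())
        ),
        session=SessionProvenance.from_doc(doc.get("session", {})),
        brick_id=doc.get("id"),
    )
    rep = validate_brick(brick, registry)
    if not rep.ok:
        raise BrickError(f"loaded brick {brick.name!r} is invalid: {rep!r}")
    return brick
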