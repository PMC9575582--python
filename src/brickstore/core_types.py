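"""Static core types: the reference backbone.

A core type (Well, Sample, Gene, ...) is a stable record schema built
from scalar contexton fields.  Core objects get permanent identifiers and
are the anchors every dynamic dataset must ultimately link to.  The set
of all objects of a type is equivalently a set of 1-D contextons (one per
field, length = number of live objects); :func:`column_view` exposes that
view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

from .contextons import Contexton, make_contexton
from .errors import DuplicateNameError, MicrotypeError
from .microtypes import Microtype, MicrotypeRegistry, ScalarKind

__all__ = [
    "CoreField",
    "CoreTypeDef",
    "CoreObject",
    "CoreTypeRegistry",
    "define_core_type",
    "column_view",
]


@dataclass(frozen=True)
class CoreField:
    name: str
    microtype: Microtype
    required: bool = False


@dataclass(frozen=True)
class CoreTypeDef:
    """Schema of one static type: ordered fields plus a primary-key field
    whose values are the unique object names others reference."""

    name: str
    fields: tuple[CoreField, ...]
    pk_field: str
    upload_roles: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.fields:
            raise MicrotypeError(f"core type {self.name!r} has no fields")
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise MicrotypeError(f"core type {self.name!r} repeats a field name")
        mt_ids = [f.microtype.id for f in self.fields]
        if len(set(mt_ids)) != len(mt_ids):
            raise MicrotypeError(
                f"core type {self.name!r} uses a microtype in two fields"
            )
        pk = self.field(self.pk_field)
        if pk is None:
            raise MicrotypeError(
                f"pk_field {self.pk_field!r} is not a field of {self.name!r}"
            )
        if not pk.required:
            raise MicrotypeError(f"pk field {pk.name!r} must be required")
        if pk.microtype.scalar_type not in (ScalarKind.STRING, ScalarKind.OTERM_REF):
            raise MicrotypeError(
                f"pk field {pk.name!r} must have string or oterm_ref scalar type"
            )

    def field(self, name: str) -> CoreField | None:
        for f in self.fields:
            if f.name == name:
                return f
        return None

    def required_fields(self) -> list[CoreField]:
        return [f for f in self.fields if f.required]

    def ref_fields(self) -> list[CoreField]:
        return [
            f for f in self.fields if f.microtype.scalar_type == ScalarKind.OBJECT_REF
        ]

    def to_doc(self) -> dict:
        return {
            "name": self.name,
            "pk_field": self.pk_field,
            "upload_roles": list(self.upload_roles),
            "fields": [
                {
                    "name": f.name,
                    "microtype": f.microtype.id,
                    "required": f.required,
                }
                for f in self.fields
            ],
        }

    @classmethod
    def from_doc(cls, doc: Mapping, registry: MicrotypeRegistry) -> "CoreTypeDef":
        return cls(
            name=doc["name"],
            fields=tuple(
                CoreField(
                    name=f["name"],
                    microtype=registry.get(f["microtype"]),
                    required=bool(f.get("required", False)),
                )
                for f in doc["fields"]
            ),
            pk_field=doc["pk_field"],
            upload_roles=tuple(doc.get("upload_roles", ())),
        )


@dataclass
class CoreObject:
    """One validated record of a core type.

    ``id`` is the permanent identifier assigned at store registration
    (``None`` for unsaved drafts).  ``superseded_by`` points to the
    replacing object's id once a newer version exists; the object itself
    is never deleted.
    """

    type_name: str
    field_values: dict[str, Contexton]
    id: str | None = None
    superseded_by: str | None = None

    @property
    def live(self) -> bool:
        return self.superseded_by is None

    def pk(self, typedef: CoreTypeDef) -> str:
        return self.field_values[typedef.pk_field].scalar_value()

    def get(self, field_name: str) -> Any:
        c = self.field_values.get(field_name)
        return None if c is None else c.scalar_value()

    def to_doc(self) -> dict:
        return {
            "kind": "core_object",
            "id": self.id,
            "type_name": self.type_name,
            "superseded_by": self.superseded_by,
            "fields": {k: c.to_doc() for k, c in self.field_values.items()},
        }

    @classmethod
    def from_doc(cls, doc: Mapping, registry: MicrotypeRegistry) -> "CoreObject":
        return cls(
            type_name=doc["type_name"],
            field_values={
                k: Contexton.from_doc(c, registry)
                for k, c in doc["fields"].items()
            },
            id=doc.get("id"),
            superseded_by=doc.get("superseded_by"),
        )


class CoreTypeRegistry:
    """Registered static type schemas; redefinition is an error (static
    types are stable by design)."""

    def __init__(self, microtypes: MicrotypeRegistry):
        self.microtypes = microtypes
        self._defs: dict[str, CoreTypeDef] = {}

    def __iter__(self):
        return iter(self._defs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def get(self, name: str) -> CoreTypeDef:
        if name not in self._defs:
            raise MicrotypeError(f"no core type named {name!r}")
        return self._defs[name]

    def define(self, typedef: CoreTypeDef) -> CoreTypeDef:
        if typedef.name in self._defs:
            raise DuplicateNameError(f"core type {typedef.name!r} already defined")
        for f in typedef.fields:
            if f.microtype.id not in [m.id for m in self.microtypes]:
                raise MicrotypeError(
                    f"field {f.name!r} uses unregistered microtype {f.microtype.id}"
                )
        self._defs[typedef.name] = typedef
        return typedef


def define_core_type(registry: CoreTypeRegistry, typedef: CoreTypeDef) -> CoreTypeDef:
    """Functional alias for :meth:`CoreTypeRegistry.define`."""
    return registry.define(typedef)


def build_core_object(
    typedef: CoreTypeDef,
    values: Mapping[str, Any],
    registry: MicrotypeRegistry,
) -> CoreObject:
    """Validate raw field values into an unsaved CoreObject draft.

    Each value is wrapped in a scalar contexton (units: for unitful
    microtypes pass ``(value, unit_term)`` tuples, otherwise the bare
    value).  Reference resolution and pk uniqueness are enforced later at
    store registration.
    """
    unknown = set(values) - {f.name for f in typedef.fields}
    if unknown:
        raise MicrotypeError(
            f"unknown field(s) for {typedef.name}: {sorted(unknown)}"
        )
    missing = [
        f.name
        for f in typedef.required_fields()
        if values.get(f.name) is None
    ]
    if missing:
        raise MicrotypeError(f"missing required field(s): {missing}")

    out: dict[str, Contexton] = {}
    for f in typedef.fields:
        if f.name not in values or values[f.name] is None:
            continue
        v = values[f.name]
        unit = None
        if isinstance(v, tuple) and len(v) == 2:
            v, unit = v
        out[f.name] = make_contexton(
            f.microtype, v, unit=unit, ontologies=registry.term_index
        )
    return CoreObject(type_name=typedef.name, field_values=out)


def column_view(
    objects: Sequence[CoreObject],
    typedef: CoreTypeDef,
    field_name: str,
    registry: MicrotypeRegistry,
) -> Contexton:
    """The 1-D contexton holding ``field_name`` across ``objects``.

    Objects missing the (optional) field contribute a null.
    """
    f = typedef.field(field_name)
    if f is None:
        raise MicrotypeError(f"{typedef.name} has no field {field_name!r}")
    vals, unit = [], None
    for o in objects:
        c = o.field_values.get(field_name)
        if c is None:
            vals.append(None)
        else:
            vals.append(c.value_at(()))
            unit = c.unit
    if unit is None and f.microtype.unitful:
        # all-null column of a unitful field: pick the first allowed unit
        unit = sorted(registry.valid_units(f.microtype), key=lambda t: t.id)[0]
    return make_contexton(f.microtype, vals, unit=unit, ontologies=registry.term_index)
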