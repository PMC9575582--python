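"""Microtypes: atomic, self-describing data types.

A microtype is the unit from which all context is built: an ontological
name, exactly one scalar type, an optional validator, and a set of allowed
measurement units (given either as explicit unit terms or as unit *classes*
whose whole subtree is allowed, e.g. "concentration unit" admitting mg/mL
and mM).  Instantiating a microtype with a value and a unit yields a
contexton (see :mod:`brickstore.contextons`).

``validate_value`` is the single total validation function: it never raises
for merely invalid data, it returns a :class:`ValidationResult` carrying
machine-readable reason codes.  A null value is valid for any microtype
(missing data) and flagged ``is_null``.

Four *system microtypes* — Data Category, Dimension Type, Values Type, and
Unit Type — must be registered before any data brick can be built; their
allowed ontological term sets define the "language" of an instance.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Mapping

from .errors import DuplicateNameError, MicrotypeError, TermNotFoundError
from .ontology import Term, TermIndex, normalize_label

__all__ = [
    "ScalarKind",
    "ValidatorSpec",
    "Microtype",
    "ValidationResult",
    "MicrotypeRegistry",
    "SystemMicrotypes",
    "validate_value",
    "register_microtype",
    "valid_units",
    "microtype_from_doc",
]

# the six allowed scalar types
SCALAR_KINDS = ("int", "float", "string", "boolean", "oterm_ref", "object_ref")
NUMERIC_KINDS = ("int", "float")


class ScalarKind:
    INT = "int"
    FLOAT = "float"
    STRING = "string"
    BOOLEAN = "boolean"
    OTERM_REF = "oterm_ref"
    OBJECT_REF = "object_ref"


# Custom predicate validators are registered here by identifier, never
# loaded from data files (no code execution via uploads).
PREDICATES: dict[str, Callable[[Any], bool]] = {
    "nonnegative": lambda v: v >= 0,
    "positive": lambda v: v > 0,
    "finite": lambda v: math.isfinite(v),
    "fraction": lambda v: 0.0 <= v <= 1.0,
}

VALIDATOR_KINDS = ("regex", "numeric_range", "predicate_name", "oterm_subtree")


@dataclass(frozen=True)
class ValidatorSpec:
    """Restriction on the allowed values of a microtype.

    kind/payload pairs:

    - ``regex`` — ``pattern`` (full-match on strings)
    - ``numeric_range`` — ``minimum``/``maximum`` (either may be None),
      ``min_open``/``max_open`` flags (closed bounds by default)
    - ``predicate_name`` — identifier into the :data:`PREDICATES` whitelist
    - ``oterm_subtree`` — ``roots``: CURIEs whose subtrees are allowed
    """

    kind: str
    pattern: str | None = None
    minimum: float | None = None
    maximum: float | None = None
    min_open: bool = False
    max_open: bool = False
    predicate: str | None = None
    roots: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in VALIDATOR_KINDS:
            raise MicrotypeError(f"unknown validator kind {self.kind!r}")
        if self.kind == "regex" and not self.pattern:
            raise MicrotypeError("regex validator requires a pattern")
        if self.kind == "numeric_range" and self.minimum is None and self.maximum is None:
            raise MicrotypeError("numeric_range validator requires a bound")
        if self.kind == "predicate_name":
            if self.predicate not in PREDICATES:
                raise MicrotypeError(
                    f"predicate {self.predicate!r} is not registered"
                )
        if self.kind == "oterm_subtree" and not self.roots:
            raise MicrotypeError("oterm_subtree validator requires root CURIEs")

    @property
    def bounded(self) -> bool:
        """True if this validator defines numeric bounds usable for clamping."""
        return self.kind == "numeric_range"

    def check(self, value: Any, index: TermIndex | None = None) -> bool:
        """Apply the restriction to a non-null, type-correct value."""
        if self.kind == "regex":
            return re.fullmatch(self.pattern, value) is not None
        if self.kind == "numeric_range":
            if self.minimum is not None:
                if value < self.minimum or (self.min_open and value == self.minimum):
                    return False
            if self.maximum is not None:
                if value > self.maximum or (self.max_open and value == self.maximum):
                    return False
            return True
        if self.kind == "predicate_name":
            return bool(PREDICATES[self.predicate](value))
        if self.kind == "oterm_subtree":
            if index is None:
                return False
            term_id = value.id if isinstance(value, Term) else value
            return any(self._in_subtree(index, r, term_id) for r in self.roots)
        raise AssertionError(self.kind)

    @staticmethod
    def _in_subtree(index: TermIndex, root: str, term_id: str) -> bool:
        return index.is_ancestor(root, term_id)

    def to_doc(self) -> dict:
        doc: dict[str, Any] = {"kind": self.kind}
        if self.kind == "regex":
            doc["pattern"] = self.pattern
        elif self.kind == "numeric_range":
            doc.update(
                minimum=self.minimum,
                maximum=self.maximum,
                min_open=self.min_open,
                max_open=self.max_open,
            )
        elif self.kind == "predicate_name":
            doc["predicate"] = self.predicate
        elif self.kind == "oterm_subtree":
            doc["roots"] = list(self.roots)
        return doc

    @classmethod
    def from_doc(cls, doc: Mapping) -> "ValidatorSpec":
        doc = dict(doc)
        kind = doc.pop("kind")
        if "roots" in doc:
            doc["roots"] = tuple(doc["roots"])
        return cls(kind=kind, **doc)


@dataclass(frozen=True)
class Microtype:
    """An atomic concept definition.  See module docstring."""

    name_term: Term
    scalar_type: str
    description: str = ""
    validator: ValidatorSpec | None = None
    allowed_units: tuple[Term, ...] = ()
    dimensionless: bool = False
    synonyms: tuple[str, ...] = ()
    ref_target: str | None = None
    non_informative: bool = False

    def __post_init__(self):
        if self.scalar_type not in SCALAR_KINDS:
            raise MicrotypeError(f"unknown scalar type {self.scalar_type!r}")
        if self.scalar_type in NUMERIC_KINDS:
            if not self.allowed_units and not self.dimensionless:
                raise MicrotypeError(
                    f"numeric microtype {self.name!r} needs allowed_units or an "
                    "explicit dimensionless flag"
                )
        if self.allowed_units and self.dimensionless:
            raise MicrotypeError(
                f"microtype {self.name!r} is dimensionless but lists units"
            )
        if self.scalar_type == ScalarKind.OBJECT_REF and not self.ref_target:
            raise MicrotypeError(
                f"object_ref microtype {self.name!r} requires ref_target"
            )
        if self.ref_target and self.scalar_type != ScalarKind.OBJECT_REF:
            raise MicrotypeError(
                f"ref_target only valid for object_ref, not {self.scalar_type}"
            )
        if self.scalar_type == ScalarKind.OTERM_REF:
            if self.validator is None or self.validator.kind != "oterm_subtree":
                raise MicrotypeError(
                    f"oterm_ref microtype {self.name!r} must carry an "
                    "oterm_subtree validator restricting its values"
                )

    @property
    def name(self) -> str:
        return self.name_term.label

    @property
    def id(self) -> str:
        return self.name_term.id

    @property
    def unitful(self) -> bool:
        return bool(self.allowed_units)

    def to_doc(self) -> dict:
        return {
            "name": self.name_term.id,
            "scalar_type": self.scalar_type,
            "description": self.description,
            "validator": self.validator.to_doc() if self.validator else None,
            "units": [t.id for t in self.allowed_units],
            "dimensionless": self.dimensionless,
            "synonyms": list(self.synonyms),
            "ref_target": self.ref_target,
            "non_informative": self.non_informative,
        }


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of validating one (value, unit) pair against a microtype."""

    ok: bool
    reasons: tuple[str, ...] = ()
    is_null: bool = False

    def __bool__(self) -> bool:
        return self.ok


# reason codes
R_TYPE = "scalar-type-mismatch"
R_VALIDATOR = "validator-failure"
R_UNIT_NOT_ALLOWED = "unit-not-allowed"
R_MISSING_UNIT = "missing-unit"
R_UNEXPECTED_UNIT = "unexpected-unit"
R_UNKNOWN_TERM = "unknown-term"

_OK = ValidationResult(True)
_NULL_OK = ValidationResult(True, is_null=True)


def _type_ok(kind: str, value: Any) -> bool:
    if kind == ScalarKind.INT:
        return isinstance(value, int) and not isinstance(value, bool)
    if kind == ScalarKind.FLOAT:
        return (isinstance(value, float) or isinstance(value, int)) and not isinstance(
            value, bool
        )
    if kind == ScalarKind.STRING:
        return isinstance(value, str)
    if kind == ScalarKind.BOOLEAN:
        return isinstance(value, bool)
    if kind == ScalarKind.OTERM_REF:
        return isinstance(value, (Term, str))
    if kind == ScalarKind.OBJECT_REF:
        return isinstance(value, str)
    raise AssertionError(kind)


def valid_units(
    registry: "MicrotypeRegistry | None",
    microtype: Microtype,
    units_ontology,
) -> set[Term]:
    """All unit terms acceptable for ``microtype``.

    Each entry of ``allowed_units`` contributes itself and its whole
    subtree (unit classes such as "concentration unit" admit every child
    unit).  Empty iff the microtype is dimensionless.  ``units_ontology``
    may be an :class:`~brickstore.ontology.Ontology` or a
    :class:`~brickstore.ontology.TermIndex`.
    """
    out: set[Term] = set()
    for t in microtype.allowed_units:
        if hasattr(units_ontology, "ontology_of"):  # TermIndex
            out |= units_ontology.expand(t)
        else:
            out |= units_ontology.expand(t)
    return out


def validate_value(
    microtype: Microtype,
    value: Any,
    unit: Term | None = None,
    ontologies: TermIndex | None = None,
) -> ValidationResult:
    """Total validation of one (value, unit) pair.  Never raises for
    invalid data; returns reason codes instead.
    """
    reasons: list[str] = []

    # unit discipline is checked even for null values
    if microtype.unitful:
        if unit is None:
            reasons.append(R_MISSING_UNIT)
        elif ontologies is not None:
            allowed = valid_units(None, microtype, ontologies)
            if unit not in allowed:
                reasons.append(R_UNIT_NOT_ALLOWED)
    else:
        if unit is not None:
            reasons.append(R_UNEXPECTED_UNIT)

    if value is None:
        return ValidationResult(not reasons, tuple(reasons), is_null=True)

    if not _type_ok(microtype.scalar_type, value):
        reasons.append(R_TYPE)
        return ValidationResult(False, tuple(reasons))

    if microtype.scalar_type == ScalarKind.OTERM_REF and ontologies is not None:
        term_id = value.id if isinstance(value, Term) else value
        try:
            ontologies.get(term_id)
        except TermNotFoundError:
            reasons.append(R_UNKNOWN_TERM)
            return ValidationResult(False, tuple(reasons))

    if microtype.validator is not None and not microtype.validator.check(
        value, ontologies
    ):
        reasons.append(R_VALIDATOR)

    return ValidationResult(not reasons, tuple(reasons))


class MicrotypeRegistry:
    """Instance-wide registry; lookup by name term, CURIE, or synonym."""

    def __init__(self, term_index: TermIndex | None = None):
        self.term_index = term_index or TermIndex()
        self._by_id: dict[str, Microtype] = {}
        self._by_label: dict[str, str] = {}  # normalized label/synonym -> CURIE

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self):
        return len(self._by_id)

    def __contains__(self, query: str) -> bool:
        try:
            self.get(query)
            return True
        except MicrotypeError:
            return False

    def register(self, spec: Microtype) -> Microtype:
        if spec.name_term.id in self._by_id:
            raise DuplicateNameError(
                f"microtype {spec.name!r} ({spec.name_term.id}) already registered"
            )
        # the name term's own synonyms are aliases too (e.g. "OD" for
        # optical density); synonyms listed on the microtype add to them
        names = (spec.name, *spec.name_term.synonyms, *spec.synonyms)
        for name in names:
            key = normalize_label(name)
            if key in self._by_label and self._by_label[key] != spec.name_term.id:
                raise DuplicateNameError(
                    f"name/synonym {name!r} already used by "
                    f"{self._by_label[key]}"
                )
        self._by_id[spec.name_term.id] = spec
        for name in names:
            self._by_label[normalize_label(name)] = spec.name_term.id
        return spec

    def get(self, query: str) -> Microtype:
        if query in self._by_id:
            return self._by_id[query]
        key = normalize_label(query)
        if key in self._by_label:
            return self._by_id[self._by_label[key]]
        raise MicrotypeError(f"no microtype named {query!r}")

    def valid_units(self, microtype: Microtype) -> set[Term]:
        return valid_units(self, microtype, self.term_index)

    def validate(self, microtype: Microtype, value, unit=None) -> ValidationResult:
        return validate_value(microtype, value, unit, self.term_index)


def register_microtype(registry: MicrotypeRegistry, spec: Microtype) -> Microtype:
    """Functional alias for :meth:`MicrotypeRegistry.register`."""
    return registry.register(spec)


@dataclass(frozen=True)
class SystemMicrotypes:
    """The four mandatory microtypes an administrator must define before
    any brick exists.  Each is an ``oterm_ref`` whose allowed values are a
    set of ontological terms chosen for the instance.  "Data Type" is a
    registered alias of Data Category.
    """

    data_category: Microtype
    dimension_type: Microtype
    values_type: Microtype
    unit_type: Microtype

    def __post_init__(self):
        for mt in (
            self.data_category,
            self.dimension_type,
            self.values_type,
            self.unit_type,
        ):
            if mt.scalar_type != ScalarKind.OTERM_REF:
                raise MicrotypeError(
                    f"system microtype {mt.name!r} must be oterm_ref"
                )

    def allowed_terms(self, which: str, index: TermIndex) -> set[Term]:
        mt: Microtype = getattr(self, which)
        out: set[Term] = set()
        for root in mt.validator.roots:
            out |= index.expand(root)
        return out


def microtype_from_doc(doc: Mapping, term_index: TermIndex) -> Microtype:
    """Build a Microtype from its JSON-dialect record.

    Record fields: ``name`` (term CURIE/label), ``scalar_type``,
    ``description``, ``validator`` (ValidatorSpec doc or null), ``units``
    (list of term queries), ``dimensionless``, ``synonyms``,
    ``ref_target``, ``non_informative``.
    """
    name_term = term_index.resolve(doc["name"])
    validator = (
        ValidatorSpec.from_doc(doc["validator"]) if doc.get("validator") else None
    )
    units = tuple(term_index.resolve(u) for u in doc.get("units", ()))
    return Microtype(
        name_term=name_term,
        scalar_type=doc["scalar_type"],
        description=doc.get("description", ""),
        validator=validator,
        allowed_units=units,
        dimensionless=bool(doc.get("dimensionless", False)),
        synonyms=tuple(doc.get("synonyms", ())),
        ref_target=doc.get("ref_target"),
        non_informative=bool(doc.get("non_informative", False)),
    )
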