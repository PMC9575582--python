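"""Upload templates and use templates.

*Upload templates* pre-fill the structure of a brick draft for a given
data category (default dimensions, default value-set microtypes/units)
and state how invalid cells are handled at import:

- ``error`` — importing invalid data is an error (the default);
- ``null``  — invalid values become missing, with a warning;
- ``clamp`` — out-of-range numeric values are moved to the nearest bound
  of the microtype's range validator, with a warning.

*Use templates* are the structural interfaces of the system: an algorithm
declares which bricks it accepts (e.g. "at least one dimension labeled
with the Time microtype"), and :func:`matches_use_template` decides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

from .bricks import DataBrick
from .errors import PolicyViolation, TemplateError
from .microtypes import (
    Microtype,
    MicrotypeRegistry,
    NUMERIC_KINDS,
    ValidatorSpec,
    validate_value,
)
from .ontology import Term, TermIndex

__all__ = [
    "POLICIES",
    "UploadTemplate",
    "UseTemplate",
    "UseConstraint",
    "BrickDraft",
    "DimDraft",
    "apply_upload_template",
    "enforce_policy",
    "matches_use_template",
]

POLICIES = ("error", "null", "clamp")


# -- draft structures (partial brick specifications) ------------------------


@dataclass
class DimDraft:
    """Skeleton of one dimension: type term + (microtype, unit) variables."""

    dim_type: Term
    variables: list[tuple[Microtype, Term | None]] = field(default_factory=list)


@dataclass
class BrickDraft:
    """A partial brick specification the upload workflow fills in.

    ``validators`` holds per-microtype stricter validators attached by an
    upload template; ``policies`` holds per-microtype invalid-data
    policies.  Both are consulted by the sheet parser.
    """

    name: str | None = None
    data_category: Term | None = None
    dims: list[DimDraft] = field(default_factory=list)
    value_sets: list[tuple[Microtype, Term | None]] = field(default_factory=list)
    overall_context: list = field(default_factory=list)
    validators: dict[str, ValidatorSpec] = field(default_factory=dict)
    policies: dict[str, str] = field(default_factory=dict)
    default_policy: str = "error"

    def policy_for(self, microtype: Microtype) -> str:
        return self.policies.get(microtype.id, self.default_policy)

    def validator_for(self, microtype: Microtype) -> ValidatorSpec | None:
        return self.validators.get(microtype.id)


@dataclass(frozen=True)
class UploadTemplate:
    """Defaults + invalid-data policy for one data category."""

    name: str
    data_category: Term
    default_dims: tuple[DimDraft, ...] = ()
    default_value_sets: tuple[tuple[Microtype, Term | None], ...] = ()
    policies: Mapping[str, str] = field(default_factory=dict)
    default_policy: str = "error"
    validators: Mapping[str, ValidatorSpec] = field(default_factory=dict)

    def __post_init__(self):
        if self.default_policy not in POLICIES:
            raise TemplateError(f"unknown policy {self.default_policy!r}")
        for mt_id, pol in self.policies.items():
            if pol not in POLICIES:
                raise TemplateError(f"unknown policy {pol!r} for {mt_id}")

    def to_doc(self) -> dict:
        return {
            "name": self.name,
            "data_category": self.data_category.id,
            "default_dims": [
                {
                    "dim_type": d.dim_type.id,
                    "variables": [
                        {"microtype": m.id, "unit": u.id if u else None}
                        for m, u in d.variables
                    ],
                }
                for d in self.default_dims
            ],
            "default_value_sets": [
                {"microtype": m.id, "unit": u.id if u else None}
                for m, u in self.default_value_sets
            ],
            "policies": dict(self.policies),
            "default_policy": self.default_policy,
            "validators": {k: v.to_doc() for k, v in self.validators.items()},
        }

    @classmethod
    def from_doc(cls, doc: Mapping, registry: MicrotypeRegistry) -> "UploadTemplate":
        idx = registry.term_index

        def pair(d):
            return (
                registry.get(d["microtype"]),
                idx.get(d["unit"]) if d.get("unit") else None,
            )

        return cls(
            name=doc["name"],
            data_category=idx.resolve(doc["data_category"]),
            default_dims=tuple(
                DimDraft(
                    idx.resolve(d["dim_type"]),
                    [pair(v) for v in d["variables"]],
                )
                for d in doc.get("default_dims", ())
            ),
            default_value_sets=tuple(
                pair(v) for v in doc.get("default_value_sets", ())
            ),
            policies=dict(doc.get("policies", {})),
            default_policy=doc.get("default_policy", "error"),
            validators={
                k: ValidatorSpec.from_doc(v)
                for k, v in doc.get("validators", {}).items()
            },
        )


def apply_upload_template(template: UploadTemplate, draft: BrickDraft) -> BrickDraft:
    """Merge template defaults *under* user-provided draft content.

    User content always wins: defaults only fill parts the draft leaves
    empty.  Stricter validators and policies are attached for the
    subsequent validation pass.  Idempotent.
    """
    if (
        draft.data_category is not None
        and draft.data_category.id != template.data_category.id
    ):
        raise TemplateError(
            f"template {template.name!r} targets category "
            f"{template.data_category.label!r}, draft has "
            f"{draft.data_category.label!r}"
        )
    out = BrickDraft(
        name=draft.name,
        data_category=draft.data_category or template.data_category,
        dims=list(draft.dims)
        or [DimDraft(d.dim_type, list(d.variables)) for d in template.default_dims],
        value_sets=list(draft.value_sets) or list(template.default_value_sets),
        overall_context=list(draft.overall_context),
        validators=dict(draft.validators),
        policies=dict(draft.policies),
        default_policy=template.default_policy,
    )
    for mt_id, v in template.validators.items():
        out.validators.setdefault(mt_id, v)
    for mt_id, p in template.policies.items():
        out.policies.setdefault(mt_id, p)
    return out


def _clamp_bounds(validator: ValidatorSpec | None):
    if validator is None or not validator.bounded:
        return None
    return validator.minimum, validator.maximum


def enforce_policy(
    microtype: Microtype,
    value: Any,
    unit: Term | None,
    policy: str,
    ontologies: TermIndex | None = None,
    extra_validator: ValidatorSpec | None = None,
) -> tuple[Any, str | None]:
    """Apply one invalid-data policy to one cell.

    Returns ``(value, warning)``: valid values pass through unchanged with
    no warning; invalid values are raised (``error``), nulled (``null``),
    or clamped to the nearest bound of the numeric range (``clamp``).
    Clamped values always re-validate.
    """
    if policy not in POLICIES:
        raise TemplateError(f"unknown policy {policy!r}")

    def check(v):
        res = validate_value(microtype, v, unit, ontologies)
        if res.ok and v is not None and extra_validator is not None:
            if not extra_validator.check(v, ontologies):
                return False, ("template-validator-failure",)
        return res.ok, res.reasons

    ok, reasons = check(value)
    if ok:
        return value, None

    detail = f"{microtype.name}: value {value!r} invalid ({','.join(reasons)})"
    if policy == "error":
        raise PolicyViolation(detail)
    if policy == "null":
        return None, f"{detail}; treated as missing"

    # clamp
    if microtype.scalar_type not in NUMERIC_KINDS or not isinstance(
        value, (int, float)
    ) or isinstance(value, bool):
        raise TemplateError(f"cannot clamp non-numeric value for {microtype.name!r}")
    validator = extra_validator if extra_validator is not None else microtype.validator
    bounds = _clamp_bounds(validator)
    if bounds is None:
        raise TemplateError(
            f"clamp policy requires a numeric_range validator on {microtype.name!r}"
        )
    lo, hi = bounds
    clamped = value
    if lo is not None and value < lo:
        clamped = lo
    if hi is not None and value > hi:
        clamped = hi
    clamped = int(clamped) if microtype.scalar_type == "int" else float(clamped)
    ok2, reasons2 = check(clamped)
    if not ok2:
        raise TemplateError(
            f"clamped value {clamped!r} still invalid for {microtype.name!r} "
            f"({','.join(reasons2)})"
        )
    return clamped, f"{detail}; clamped to {clamped!r}"


# -- use templates -----------------------------------------------------------


@dataclass(frozen=True)
class UseConstraint:
    """One structural requirement on an acceptable brick.

    Any subset of the predicates may be set; all set predicates of one
    constraint must hold (for dimension/value-set predicates: some
    dimension / some value set satisfies it).
    """

    requires_dimension_with_microtype: str | None = None  # CURIE
    requires_value_set_scalar_type: str | None = None
    requires_value_set_microtype: str | None = None  # CURIE
    min_dims: int | None = None
    max_dims: int | None = None

    def check(self, brick: DataBrick) -> str | None:
        """None if satisfied, else a human-readable failure reason."""
        if self.requires_dimension_with_microtype is not None:
            want = self.requires_dimension_with_microtype
            if not any(
                v.microtype.id == want for d in brick.dims for v in d.variables
            ):
                return f"no dimension labeled with microtype {want}"
        if self.requires_value_set_scalar_type is not None:
            want = self.requires_value_set_scalar_type
            if not any(
                vs.microtype.scalar_type == want for vs in brick.value_sets
            ):
                return f"no value set with scalar type {want}"
        if self.requires_value_set_microtype is not None:
            want = self.requires_value_set_microtype
            if not any(vs.microtype.id == want for vs in brick.value_sets):
                return f"no value set with microtype {want}"
        if self.min_dims is not None and brick.ndim < self.min_dims:
            return f"fewer than {self.min_dims} dimensions"
        if self.max_dims is not None and brick.ndim > self.max_dims:
            return f"more than {self.max_dims} dimensions"
        return None


@dataclass(frozen=True)
class UseTemplate:
    """A structural interface: the conjunction of constraints a brick must
    satisfy to be accepted by an algorithm."""

    name: str
    constraints: tuple[UseConstraint, ...] = ()

    def to_doc(self) -> dict:
        out = []
        for c in self.constraints:
            entry = {
                k: v
                for k, v in (
                    ("requires_dimension_with_microtype", c.requires_dimension_with_microtype),
                    ("requires_value_set_scalar_type", c.requires_value_set_scalar_type),
                    ("requires_value_set_microtype", c.requires_value_set_microtype),
                    ("min_dims", c.min_dims),
                    ("max_dims", c.max_dims),
                )
                if v is not None
            }
            out.append(entry)
        return {"name": self.name, "constraints": out}

    @classmethod
    def from_doc(cls, doc: Mapping) -> "UseTemplate":
        return cls(
            name=doc["name"],
            constraints=tuple(
                UseConstraint(**c) for c in doc.get("constraints", ())
            ),
        )


def matches_use_template(
    brick: DataBrick, template: UseTemplate
) -> tuple[bool, str]:
    """True iff every constraint is satisfied; otherwise the first
    failing constraint's explanation.  A template with no constraints
    matches every valid brick."""
    for i, c in enumerate(template.constraints):
        why = c.check(brick)
        if why is not None:
            return False, f"constraint {i} of {template.name!r} failed: {why}"
    return True, f"matches {template.name!r}"
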