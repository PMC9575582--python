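"""Contextons: instantiated microtypes carrying values and a unit.

A contexton is the trio (microtype, value-or-array, unit).  It is
*self-validating*: every non-null value is checked against the microtype's
scalar type, validator, and allowed units at construction time,
independently of any larger structure the contexton later ends up in.
Scalar contextons describe whole datasets (and act as modifiers in
compound contextons), 1-D contextons label dimension axes, and N-D
contextons hold the data values of a brick.

Nulls (missing data) are first-class: they are carried in an explicit
boolean mask alongside the value array, never as a sentinel value, so no
real value can collide with "missing".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .errors import ContextonValidationError, MicrotypeError
from .microtypes import (
    Microtype,
    MicrotypeRegistry,
    R_TYPE as R_TYPE_MISMATCH,
    ScalarKind,
    ValidationResult,
    validate_value,
)
from .ontology import Term, TermIndex

__all__ = ["Contexton", "make_contexton", "contexton_shape"]

_FLOAT = ScalarKind.FLOAT
_INT = ScalarKind.INT


def _is_null(v: Any) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    return False


def _coerce(kind: str, v: Any) -> Any:
    """Normalize one non-null raw value before validation/storage."""
    if isinstance(v, np.generic):
        v = v.item()
    if kind == ScalarKind.OTERM_REF and isinstance(v, Term):
        return v.id
    if kind == _FLOAT and isinstance(v, int) and not isinstance(v, bool):
        return float(v)
    return v


@dataclass(frozen=True)
class Contexton:
    """A validated (microtype, values, unit) trio, optionally compound.

    ``values`` is a numpy array (0-d for scalars); ``mask`` flags nulls.
    ``modifiers`` are scalar contextons refining the primary concept
    (e.g. concentration *of nitrate*, *at 25 °C*, *log2-scaled*).
    Instances are built via :func:`make_contexton`, which performs the
    self-validation; do not mutate the arrays.
    """

    microtype: Microtype
    values: np.ndarray
    mask: np.ndarray
    unit: Term | None = None
    modifiers: tuple["Contexton", ...] = ()

    # -- structure ---------------------------------------------------------
    @property
    def shape(self) -> list[int]:
        return list(self.values.shape)

    @property
    def is_scalar(self) -> bool:
        return self.values.ndim == 0

    @property
    def size(self) -> int:
        return int(self.values.size)

    @property
    def is_compound(self) -> bool:
        return bool(self.modifiers)

    @property
    def label(self) -> str:
        u = f" ({self.unit.label})" if self.unit is not None else ""
        return f"{self.microtype.name}{u}"

    def value_at(self, idx=()) -> Any:
        """Value at a coordinate, ``None`` where masked."""
        if self.mask[idx]:
            return None
        v = self.values[idx]
        return v.item() if isinstance(v, np.generic) else v

    def scalar_value(self) -> Any:
        if not self.is_scalar:
            raise MicrotypeError("not a scalar contexton")
        return self.value_at(())

    def iter_values(self):
        """Yield (coordinate tuple, value-or-None) in row-major order."""
        for idx in np.ndindex(self.values.shape):
            yield idx, self.value_at(idx)

    def to_list(self):
        """Nested lists with ``None`` at masked positions (JSON-ready)."""

        def rec(idx):
            if len(idx) == self.values.ndim:
                return self.value_at(idx)
            return [rec(idx + (i,)) for i in range(self.values.shape[len(idx)])]

        return rec(())

    # -- equality ----------------------------------------------------------
    def _key(self):
        return (
            self.microtype.id,
            self.unit.id if self.unit else None,
            tuple(self.values.shape),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Contexton):
            return NotImplemented
        if self._key() != other._key():
            return False
        if not np.array_equal(self.mask, other.mask):
            return False
        keep = ~self.mask
        if self.values.dtype != other.values.dtype:
            return False
        if not np.array_equal(self.values[keep], other.values[keep]):
            return False
        # modifiers are unordered for equality
        if len(self.modifiers) != len(other.modifiers):
            return False
        unmatched = list(other.modifiers)
        for m in self.modifiers:
            for i, o in enumerate(unmatched):
                if m == o:
                    del unmatched[i]
                    break
            else:
                return False
        return True

    def __hash__(self):
        return hash(self._key())

    # -- serialization -----------------------------------------------------
    def to_doc(self) -> dict:
        doc: dict[str, Any] = {
            "microtype": self.microtype.id,
            "unit": self.unit.id if self.unit else None,
            "shape": self.shape,
            "values": self.to_list(),
        }
        if self.modifiers:
            doc["modifiers"] = [m.to_doc() for m in self.modifiers]
        return doc

    @classmethod
    def from_doc(cls, doc: Mapping, registry: MicrotypeRegistry) -> "Contexton":
        mt = registry.get(doc["microtype"])
        unit = registry.term_index.get(doc["unit"]) if doc.get("unit") else None
        modifiers = tuple(
            cls.from_doc(m, registry) for m in doc.get("modifiers", ())
        )
        values = doc["values"]
        if doc.get("shape") == [] and not isinstance(values, list):
            pass  # scalar stays scalar
        return make_contexton(
            mt,
            values,
            unit=unit,
            modifiers=modifiers,
            ontologies=registry.term_index,
        )

    def revalidate(self, ontologies: TermIndex) -> list[tuple[tuple, ValidationResult]]:
        """Re-run self-validation; returns the failing (coord, result) pairs.

        Empty for any contexton built by :func:`make_contexton`
        (idempotence of self-validation).
        """
        bad = []
        for idx, v in self.iter_values():
            res = validate_value(self.microtype, v, self.unit, ontologies)
            if not res.ok:
                bad.append((idx, res))
        return bad


_DTYPES = {
    ScalarKind.INT: np.int64,
    ScalarKind.FLOAT: np.float64,
    ScalarKind.STRING: object,
    ScalarKind.BOOLEAN: object,
    ScalarKind.OTERM_REF: object,
    ScalarKind.OBJECT_REF: object,
}


def make_contexton(
    microtype: Microtype,
    values: Any,
    unit: Term | None = None,
    modifiers: Sequence[Contexton] = (),
    ontologies: TermIndex | None = None,
) -> Contexton:
    """Build and self-validate a contexton.

    ``values`` may be a scalar, nested lists, or a numpy array; ``None``
    (or NaN for floats) marks missing data.  On any invalid value the full
    set of per-value reason codes is raised in a
    :class:`~brickstore.errors.ContextonValidationError`.
    """
    needs_index = (
        microtype.unitful or microtype.scalar_type == ScalarKind.OTERM_REF
    )
    if needs_index and ontologies is None:
        raise MicrotypeError(
            f"validating {microtype.name!r} requires the instance term index"
        )

    raw = np.asarray(values, dtype=object)
    mask = np.empty(raw.shape, dtype=bool)
    store = np.empty(raw.shape, dtype=_DTYPES[microtype.scalar_type])
    failures: list[tuple[tuple | None, ValidationResult]] = []

    for idx in np.ndindex(raw.shape):
        v = raw[idx]
        if isinstance(v, np.generic):
            v = v.item()
        if _is_null(v):
            mask[idx] = True
            res = validate_value(microtype, None, unit, ontologies)
            if not res.ok:
                failures.append((idx, res))
            if microtype.scalar_type == _FLOAT:
                store[idx] = np.nan
            elif microtype.scalar_type == _INT:
                store[idx] = 0
            else:
                store[idx] = None
            continue
        mask[idx] = False
        v = _coerce(microtype.scalar_type, v)
        res = validate_value(microtype, v, unit, ontologies)
        if not res.ok:
            failures.append((idx, res))
            if R_TYPE_MISMATCH in res.reasons:
                continue  # cannot be stored in the typed array; raised below
        store[idx] = v

    for m in modifiers:
        if not isinstance(m, Contexton):
            raise MicrotypeError("modifiers must be Contexton instances")
        if not m.is_scalar:
            failures.append(
                (None, ValidationResult(False, ("modifier-not-scalar",)))
            )
        if m.modifiers:
            failures.append(
                (None, ValidationResult(False, ("modifier-nesting-too-deep",)))
            )

    if failures:
        raise ContextonValidationError(
            f"{len(failures)} invalid entr{'y' if len(failures)==1 else 'ies'} "
            f"for microtype {microtype.name!r}: "
            + "; ".join(
                f"{idx}: {','.join(r.reasons)}" for idx, r in failures[:5]
            ),
            failures=failures,
        )

    store.setflags(write=False)
    mask.setflags(write=False)
    return Contexton(
        microtype=microtype,
        values=store,
        mask=mask,
        unit=unit,
        modifiers=tuple(modifiers),
    )


def contexton_shape(contexton: Contexton) -> list[int]:
    """[] for scalar, [n] for 1-D, [n1..nk] for N-D."""
    return contexton.shape
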