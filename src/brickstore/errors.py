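"""Exception hierarchy.

Every error raised by the library derives from :class:`BrickstoreError` so
callers (and the CLI) can distinguish data problems from programming bugs.
"""


class BrickstoreError(Exception):
    """Base class for all library errors."""


class OntologyParseError(BrickstoreError):
    """Malformed ontology document (bad stanza, missing id, bad CURIE)."""


class OntologyIntegrityError(BrickstoreError):
    """Structural violation: dangling parent, duplicate id, or cycle."""


class TermNotFoundError(BrickstoreError, KeyError):
    """Query matched no term."""


class AmbiguousTermError(BrickstoreError):
    """Query matched more than one term; caller must use a CURIE."""


class MicrotypeError(BrickstoreError):
    """Invalid microtype definition or registry violation."""


class DuplicateNameError(MicrotypeError):
    """A name that must be unique (microtype, core type, pk) was reused."""


class ContextonValidationError(BrickstoreError):
    """A contexton failed self-validation; carries per-value reason codes."""

    def __init__(self, message, failures=None):
        super().__init__(message)
        #: list of (index-or-None, ValidationResult) for failing values
        self.failures = failures or []


class BrickError(BrickstoreError):
    """Structural brick violation (shape, missing mandatory context, ...)."""


class StoreError(BrickstoreError):
    """Provenance-store violation (anchoring, dangling ref, unknown id)."""


class TemplateError(BrickstoreError):
    """Upload/use template misuse (category mismatch, bad policy)."""


class PolicyViolation(TemplateError):
    """A value rejected under the ``error`` invalid-data policy."""


class SheetError(BrickstoreError):
    """Template-sheet layout or header/schema mismatch."""
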