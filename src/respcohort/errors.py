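"""Exception hierarchy for the toolkit."""


class RespcohortError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(RespcohortError):
    """A file is missing required columns or is otherwise structurally invalid."""


class ValidationError(RespcohortError):
    """Content-level validation failed (duplicates, empty inputs, bad enums)."""


class ConfigurationError(RespcohortError):
    """A codelist/dialect combination cannot support the requested operation."""


class IntegrityError(RespcohortError):
    """Referential integrity between linked tables is broken."""
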