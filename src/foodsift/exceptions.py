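"""Exception hierarchy.

All toolkit errors derive from :class:`FoodSiftError` so callers can catch
one base class; the CLI maps each subclass to a distinct exit message.
"""


class FoodSiftError(Exception):
    """Base class for all foodsift errors."""


class SchemaError(FoodSiftError):
    """An input table is missing a required column or has a malformed header."""


class IntegrityError(FoodSiftError):
    """A table-level integrity constraint is violated (e.g. duplicate ids)."""


class RowParseError(FoodSiftError):
    """A single row could not be parsed; carries the 0-based row index."""

    def __init__(self, row_index: int, message: str):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


class ValidationError(FoodSiftError):
    """A value or object violates a domain invariant."""


class DomainError(FoodSiftError):
    """An operation was called outside its mathematical domain."""


class ConfigError(FoodSiftError):
    """A configuration file or parameter set is malformed."""


class UsageError(FoodSiftError):
    """An API precondition was violated by the caller."""
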