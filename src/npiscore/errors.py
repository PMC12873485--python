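"""Exception hierarchy.

All package errors derive from :class:`NpiScoreError` so callers can catch
one base class. The distinction that matters scientifically is between
*input-domain* problems (a negative sugar amount), *configuration* problems
(a malformed threshold table) and *unscorable* items (a food lacking the
nutrition information the model requires — these are omitted from analysis
rather than treated as failures).
"""

from __future__ import annotations


class NpiScoreError(Exception):
    """Base class for all package errors."""


class InputDomainError(NpiScoreError, ValueError):
    """A value lies outside the model's input domain (e.g. negative amount)."""


class ConfigurationError(NpiScoreError):
    """Threshold tables, taxonomy or rules are malformed or inconsistent."""


class UnscorableError(NpiScoreError):
    """The item cannot be scored; carries the missing fields."""

    def __init__(self, message: str, missing: tuple[str, ...] = ()):
        super().__init__(message)
        self.missing = tuple(missing)


class SchemaError(NpiScoreError):
    """An input file violates its documented schema; carries row context."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row
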