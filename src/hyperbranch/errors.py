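"""Exception hierarchy.

All user-facing failures derive from :class:`HyperbranchError` so callers
(and the CLI) can catch one type; validation failures additionally derive
from ``ValueError`` so they behave naturally in plain library use.
"""


class HyperbranchError(Exception):
    """Base class for all package errors."""


class ValidationError(HyperbranchError, ValueError):
    """A user-supplied parameter violates its documented constraint."""


class StructureError(HyperbranchError):
    """A topology is not a valid rooted tree (cycle, disconnect, bad parent)."""


class GenerationError(HyperbranchError):
    """Stochastic growth exhausted its attempt budget for a (DP, DB) pair."""


class PackingError(HyperbranchError):
    """Molecules or solvent could not be placed without overlap."""


class Mol2ParseError(HyperbranchError):
    """A mol2 file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class TemplateError(HyperbranchError):
    """A repeat-unit template or its attachment records are inconsistent."""


class MapFileError(HyperbranchError):
    """The role->template map file is malformed or incomplete."""
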