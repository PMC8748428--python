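"""Typed exceptions raised across the package.

Every malformed input raises one of these instead of being silently
coerced; callers can catch :class:`EquiclockError` to handle all of them.
"""


class EquiclockError(Exception):
    """Base class for all package errors."""


class ValidationError(EquiclockError, ValueError):
    """A container violates one of its invariants (e.g. beta outside [0,1])."""


class AlignmentError(EquiclockError, ValueError):
    """Identifiers of two containers that must agree do not match."""


class FormatError(EquiclockError, ValueError):
    """A file on disk does not conform to the expected dialect."""


class DomainError(EquiclockError, ValueError):
    """A scalar argument lies outside the mathematical domain of an operation."""


class LookupSpeciesError(EquiclockError, KeyError):
    """A species is missing from the species table / transform parameters."""


class DegenerateFitError(EquiclockError, ValueError):
    """The response or design is degenerate (constant y, empty design)."""


class FoldError(EquiclockError, ValueError):
    """A cross-validation fold cannot be formed (too few samples/species)."""


class DesignError(EquiclockError, ValueError):
    """A regression design is rank deficient or misses a required group."""


class ConfigError(EquiclockError, ValueError):
    """A simulation or workflow configuration is invalid or infeasible."""
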