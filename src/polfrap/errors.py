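"""Exception hierarchy.

All user-facing errors derive from :class:`PolfrapError` so callers can catch
one type at pipeline boundaries.
"""


class PolfrapError(Exception):
    """Base class for all polfrap errors."""


class InputError(PolfrapError, ValueError):
    """Malformed or inconsistent user input (lengths, grids, empty lists)."""


class ConfigError(PolfrapError, ValueError):
    """Invalid or inconsistent configuration values."""


class ModelError(PolfrapError, ValueError):
    """Kinetic model violates its invariants (fractions, rates)."""


class DegenerateTraceError(PolfrapError, ValueError):
    """A trace cannot be normalized (non-positive pre-bleach reference)."""
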