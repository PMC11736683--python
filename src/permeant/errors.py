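"""Exception hierarchy.

All package errors derive from :class:`PermeantError` so callers can catch
one base class; most also derive from the closest builtin (ValueError /
IOError) so generic handling keeps working.
"""


class PermeantError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PermeantError, ValueError):
    """An input object violates one of its documented invariants."""


class FormatError(PermeantError, ValueError):
    """A trajectory or table file could not be parsed.

    Carries ``frame`` (0-based) when the offending record is known.
    """

    def __init__(self, message, frame=None):
        if frame is not None:
            message = f"{message} (frame {frame})"
        super().__init__(message)
        self.frame = frame


class UnwrapError(PermeantError, ValueError):
    """Unwrapped coordinates are required but only wrapped ones exist."""


class LabelingError(PermeantError, ValueError):
    """A required particle role label is missing from the trajectory."""


class GeometryError(PermeantError, ValueError):
    """Membrane geometry is inconsistent with the simulation box."""


class ReferenceRegionError(PermeantError, ValueError):
    """The reference (water) region contains no samples."""


class StabilityError(PermeantError, ValueError):
    """Integrator settings would produce an unstable update."""


class ConfigurationError(PermeantError, ValueError):
    """A required parameter is missing or inconsistent."""
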