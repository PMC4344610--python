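"""Exception hierarchy shared across the package.

All glyconf errors derive from :class:`GlyconfError` so callers can catch
the package's failures with one clause; subclasses also inherit from the
closest builtin (``ValueError``/``KeyError``) so generic handling keeps
working.
"""


class GlyconfError(Exception):
    """Base class for all glyconf errors."""


class DegenerateGeometryError(GlyconfError, ValueError):
    """Collinear or coincident atoms make an angle/dihedral undefined."""


class AtomLookupError(GlyconfError, KeyError):
    """A required atom identifier is missing from a frame or ensemble."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class ConfigurationError(GlyconfError, ValueError):
    """An incomplete or inconsistent configuration table."""


class ValidationError(GlyconfError, ValueError):
    """Invalid argument values (weights, steps, tolerances, ...)."""


class EmptyInputError(GlyconfError, ValueError):
    """An operation that needs at least one element received none."""


class PairingError(GlyconfError, ValueError):
    """Experimental and calculated records could not be matched 1:1."""


class NormalizationError(GlyconfError, ValueError):
    """A reference quantity used for normalization is zero or invalid."""


class CapabilityError(GlyconfError, ValueError):
    """The requested computation needs inputs the supplied data lack
    (e.g. NOE prediction from a torsion-only ensemble)."""


class EnsembleParseError(GlyconfError, ValueError):
    """A coordinate/torsion file could not be parsed."""


class UnknownPresetError(GlyconfError, KeyError):
    """An unregistered preset / plugin name was requested."""

    def __str__(self) -> str:
        return Exception.__str__(self)
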