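"""Exception types shared across the package."""


class ThermleafError(Exception):
    """Base class for package-specific errors."""


class UnitMismatchError(ThermleafError, ValueError):
    """Kinetic parameters carry incompatible unit labels for one equation."""


class ParameterRangeError(ThermleafError, OverflowError):
    """An Arrhenius evaluation would overflow (absurd scaling constant)."""


class CompositionError(ThermleafError, ValueError):
    """Two strategies override the same FvCB parameter role."""


class UndefinedGainError(ThermleafError, ValueError):
    """Relative gain requested against a non-positive reference rate."""


class ConfigError(ThermleafError, ValueError):
    """Configuration file violates the schema or a model invariant."""
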