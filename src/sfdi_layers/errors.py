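"""Typed exceptions shared across the package."""


class SfdiLayersError(Exception):
    """Base class for all package errors."""


class DomainError(SfdiLayersError, ValueError):
    """An input violates a documented precondition (names the offending field)."""


class SingularConfigurationError(SfdiLayersError):
    """A fluence-model denominator vanished (mu_eff_prime too close to a
    transport rate).  Perturb fx slightly to move off the singular point."""


class InvalidFluenceError(SfdiLayersError):
    """A model produced a non-physical fluence (negative, or non-positive
    total phi^2 integral); alpha is undefined for such a profile."""


class CalibrationError(SfdiLayersError):
    """Reference amplitudes unusable (zero/negative over too many pixels)."""


class InversionError(SfdiLayersError):
    """The homogeneous optical-property fit failed to converge."""


class GeneratorError(SfdiLayersError):
    """Synthetic-data fixed-point iteration failed to converge."""
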