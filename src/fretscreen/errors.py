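"""Exception hierarchy shared across the package."""


class FretScreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FretScreenError):
    """A tabular input file does not have the expected columns/structure."""


class ValidationError(FretScreenError):
    """Input values violate a documented invariant (roles, coordinates, ranges)."""


class DuplicateReadError(ValidationError):
    """The same (well, excitation, emission) appears more than once on a plate."""


class MissingChannelError(FretScreenError):
    """A required (excitation, emission) read is absent from a well."""


class MissingBlankError(FretScreenError):
    """A channel present in sample wells has no blank wells to subtract."""


class UndefinedRatioError(FretScreenError):
    """Ratiometric signal undefined (donor-channel intensity <= 0)."""


class CalibrationError(FretScreenError):
    """Bleed-through calibration impossible (zero-denominator wells)."""


class FitError(FretScreenError):
    """A nonlinear fit failed or its input was degenerate."""


class QCError(FretScreenError):
    """Plate does not carry the controls required for quality statistics."""


class ConfigurationError(FretScreenError):
    """A threshold/configuration value makes an operation undefined."""


class ReconciliationError(FretScreenError):
    """The two parallel assays do not cover the same compound library."""


class EquilibriumError(FretScreenError):
    """Mass-action equilibrium solver failed to converge."""


class NoTransitionError(FretScreenError):
    """Melt curve has no usable unfolding transition."""
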