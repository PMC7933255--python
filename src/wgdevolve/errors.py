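"""Exception hierarchy shared across the package."""


class WgdEvolveError(Exception):
    """Base class for all package errors."""


class FormatError(WgdEvolveError, ValueError):
    """A file does not conform to its expected tabular dialect."""


class ValidationError(WgdEvolveError, ValueError):
    """Parsed data violate a structural invariant (overlaps, bad ranges)."""


class ParameterError(WgdEvolveError, ValueError):
    """Model parameters outside their admissible domain."""


class UnrepresentableStateError(WgdEvolveError, ValueError):
    """An observed copy number exceeds the support of the model."""


class FitError(WgdEvolveError, RuntimeError):
    """Maximum-likelihood fitting could not produce a finite optimum."""


class InsufficientDataError(WgdEvolveError, ValueError):
    """Too few observations for the requested statistic."""


class ConfigError(WgdEvolveError, ValueError):
    """A run or simulation configuration is infeasible or incomplete."""
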