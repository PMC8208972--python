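"""Exception hierarchy for istlung."""


class ISTError(Exception):
    """Base class for all istlung errors."""


class ConfigurationError(ISTError, ValueError):
    """Invalid model, lung or optimiser configuration."""


class UnphysicalForcingError(ISTError, ValueError):
    """Sinewave forcing drives inspired fractions outside [0, 1)."""


class UnphysicalDistributionError(ISTError, ValueError):
    """Lognormal spec produces non-finite compartment weights."""


class UnidentifiableSeriesError(ISTError, ValueError):
    """Breath series carries no usable oscillation (zero amplitude)."""


class FitConvergenceError(ISTError, RuntimeError):
    """Inner single-compartment least squares failed to converge.

    Carries the final residual vector in ``residual``.
    """

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class ForwardModelError(ISTError, RuntimeError):
    """Forward IST map failed for a candidate parameter set."""


class UndefinedInputError(ISTError, ValueError):
    """Operation called on empty or single-class input where undefined."""
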