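"""Exception hierarchy shared across the package."""


class SeedlongError(Exception):
    """Base class for all package-specific errors."""


class ParameterDomainError(SeedlongError, ValueError):
    """A decay-curve parameter lies outside its mathematical domain."""


class DataError(SeedlongError, ValueError):
    """An input table or record violates a declared invariant."""


class DegenerateAssayError(SeedlongError, ValueError):
    """An assay carries no usable signal for curve fitting."""


class FitError(SeedlongError, RuntimeError):
    """Nonlinear optimisation failed from every starting point."""


class PerfectFitError(SeedlongError, ValueError):
    """RSS is exactly zero; information criteria are undefined.

    Callers should report a perfect fit instead of AIC/BIC.
    """
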