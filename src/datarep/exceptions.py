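"""Exception types shared across the package."""


class DatarepError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DatarepError, ValueError):
    """An argument violates a documented precondition."""


class ImproperDistributionError(DatarepError, ValueError):
    """A beta shape parameter is non-positive or non-finite.

    A beta density with such shapes does not integrate to one, so every
    divergence built on it is undefined.  The offending parameter is named
    in the message.
    """


class DegenerateRatioError(DatarepError, ZeroDivisionError):
    """The denominator KL term of the criterion ratio is zero.

    This happens only when the separability distribution coincides exactly
    with the dissimilar-benchmark prior, which signals a configuration
    error rather than a property of the data.
    """


class NumericIntegrationError(DatarepError, ArithmeticError):
    """Adaptive quadrature failed to reach the requested tolerance."""
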