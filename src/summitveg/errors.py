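"""Exception hierarchy shared across the package."""


class SummitVegError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SummitVegError):
    """Input records violate a schema invariant (duplicates, out-of-range values)."""


class ParseError(SummitVegError):
    """A delimited-text input could not be parsed; carries the offending location."""


class ConfigurationError(SummitVegError):
    """A run or simulation configuration is inconsistent or incomplete."""


class EmptyInputError(SummitVegError):
    """An operation received an empty selection where data are required."""


class DomainError(SummitVegError):
    """Arguments are outside the mathematical domain of an operation."""


class MatchingError(SummitVegError):
    """Sites or quadrats could not be matched across surveys; lists the orphans."""


class DegenerateDesignError(SummitVegError):
    """A statistical design is degenerate (constant factor, no residual df, ...)."""


class RankDeficiencyError(DegenerateDesignError):
    """A linear-model design matrix is rank deficient; names aliased terms."""


class ImputationError(SummitVegError):
    """Gap filling failed; carries the unserviceable time slots."""


class AttributeLookupError(SummitVegError):
    """Species lacking required attributes (e.g. thermic rank); lists them."""
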