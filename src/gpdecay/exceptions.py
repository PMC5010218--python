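"""Exception hierarchy for gpdecay."""


class GpdecayError(Exception):
    """Base class for all package errors."""


class ParseError(GpdecayError):
    """A genotype or phenotype file could not be parsed."""


class ValidationError(GpdecayError, ValueError):
    """Input violates a documented precondition or type invariant."""


class MonomorphicMarkerError(ValidationError):
    """A marker with zero variance was passed where polymorphism is required."""


class UndefinedCorrelationError(ValidationError):
    """Pearson correlation requested for a constant vector."""


class DegenerateSplitError(GpdecayError):
    """Clustering produced an empty or unusable partition."""


class ExtrapolationError(GpdecayError):
    """A curve query outside the observed range; use the linear fit instead."""
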