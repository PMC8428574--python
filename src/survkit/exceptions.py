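"""Exception hierarchy shared across the package."""


class SurvkitError(Exception):
    """Base class for all survkit errors."""


class ValidationError(SurvkitError, ValueError):
    """Malformed input data (shapes, domains, missing values)."""


class ShapeError(ValidationError):
    """Array dimensions do not agree."""


class ConvergenceError(SurvkitError, RuntimeError):
    """An iterative fit failed to converge (including monotone-likelihood divergence)."""


class ChannelError(SurvkitError, ValueError):
    """A prediction lacks the channel a measure or compositor requires."""


class ScoringError(SurvkitError, ValueError):
    """A measure cannot be evaluated on the given data (e.g. no comparable pairs)."""
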