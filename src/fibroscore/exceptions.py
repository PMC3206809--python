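"""Exception hierarchy for fibroscore."""


class FibroscoreError(Exception):
    """Base class for all fibroscore errors."""


class ValidationError(FibroscoreError, ValueError):
    """A table or parameter violates the data-model contract."""


class ParseError(FibroscoreError, ValueError):
    """A file could not be parsed; carries offending line numbers where known."""


class InsufficientDataError(FibroscoreError, ValueError):
    """Too few observations for the requested statistic."""


class ConfigurationError(FibroscoreError, ValueError):
    """Inconsistent configuration, e.g. a marker missing from the direction table."""


class OptimizationError(FibroscoreError, RuntimeError):
    """Weight optimization failed to reach perfect rank concordance.

    Attributes
    ----------
    best_rho : float
        The highest Spearman rho attained over the whole weight lattice.
    """

    def __init__(self, message: str, best_rho: float):
        super().__init__(message)
        self.best_rho = best_rho
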