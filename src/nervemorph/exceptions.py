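"""Exception types used across nervemorph."""


class NerveMorphError(Exception):
    """Base class for package errors."""


class ConfigurationError(NerveMorphError, ValueError):
    """A configuration value is missing or out of its allowed range.

    The message always names the offending field.
    """


class PackingError(NerveMorphError, RuntimeError):
    """Fibre placement could not reach the requested density.

    Attributes
    ----------
    achieved : int
        Number of fibres successfully placed before giving up.
    """

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved


class DesignError(NerveMorphError, ValueError):
    """A model design matrix is malformed (dimension mismatch, rank
    deficiency, non-nested comparison)."""


class FitError(NerveMorphError, RuntimeError):
    """An iterative fit failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
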