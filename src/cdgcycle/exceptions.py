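"""Exception hierarchy shared across the package."""


class CdgcycleError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CdgcycleError, ValueError):
    """A model parameter or argument violates its documented contract."""


class AlignmentError(CdgcycleError, ValueError):
    """Measurement timepoints do not match the composition matrix rows."""


class ConditioningError(CdgcycleError, ValueError):
    """The linear system is rank deficient / too ill-conditioned to solve."""


class ParseError(CdgcycleError, ValueError):
    """An input file could not be parsed; the message names the offending
    row or column where known."""
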