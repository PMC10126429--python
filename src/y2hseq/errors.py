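"""Exception hierarchy shared across the package."""


class Y2HSeqError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(Y2HSeqError):
    """A configuration value violates its contract."""


class InvalidInputError(Y2HSeqError):
    """Input data violate a precondition (negative counts, empty library, ...)."""


class InconsistencyError(Y2HSeqError):
    """Two inputs that must agree (e.g. FPKM denominator vs count total) do not."""


class SimulationExhaustedError(Y2HSeqError):
    """The colony sampler could not produce the requested number of survivors
    within its draw budget (e.g. empty-bait screen with no self-activators and
    zero leak probability)."""


class MappedTotalZeroError(InvalidInputError):
    """FPKM is undefined because zero reads were assigned."""
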