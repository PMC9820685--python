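"""Exception hierarchy shared across the package."""


class MirsigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirsigError):
    """A file does not conform to its documented dialect."""


class ConsistencyError(FormatError):
    """Cross-file labels disagree (e.g. a count column missing from metadata)."""


class DomainError(MirsigError, ValueError):
    """An argument is outside its documented domain."""


class DesignError(MirsigError):
    """The sample design cannot support the requested computation."""


class DataError(MirsigError):
    """Input values are unusable (non-finite, negative counts, ...)."""


class DegenerateInputError(MirsigError):
    """Input is formally valid but degenerate (e.g. a zero housekeeping count)."""


class PairingError(MirsigError):
    """A patient lacks the primary/metastasis pair needed for a paired statistic."""


class UndefinedStatisticError(MirsigError):
    """The requested statistic is undefined on this input (e.g. zero variance)."""


class UnknownMiRNAError(MirsigError):
    """A signature miRNA is not annotated on any panel probe."""


class EffectConflictError(MirsigError):
    """One probe is annotated to planted miRNAs with opposite directions."""
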