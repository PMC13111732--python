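"""Exception types shared across the package."""


class AlueditError(Exception):
    """Base class for package-specific errors."""


class FormatError(AlueditError, ValueError):
    """Malformed input file or alignment record."""


class CapacityError(AlueditError, ValueError):
    """A request exceeds what the reference can host (e.g. not enough
    eligible Alu adenosines to plant the requested sites)."""


class UndefinedIndexError(AlueditError, ValueError):
    """The Alu editing index is undefined: no informative A/T bases."""


class InsufficientDataError(AlueditError, ValueError):
    """Too few donors/conditions with complete pairs to fit the model."""


class DegenerateDataError(AlueditError, ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


class InconsistencyError(AlueditError, ValueError):
    """Internally inconsistent inputs (e.g. editing events recorded for a
    sample with zero mapped reads)."""
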