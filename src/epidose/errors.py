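"""Exception hierarchy shared across the package."""


class EpidoseError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EpidoseError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(EpidoseError, ValueError):
    """Too few data points to perform a fit or estimate."""


class NumericDomainError(EpidoseError, ArithmeticError):
    """A computation left its valid numeric domain (overflow/degeneracy)."""


class StateError(EpidoseError, RuntimeError):
    """Operation incompatible with the object's current state."""


class RangeError(EpidoseError, ValueError):
    """A lookup outside the tabulated support."""


class CostGuardError(EpidoseError, RuntimeError):
    """A test-only oracle was invoked on a problem too large to brute-force."""


class EmptyStructureError(EpidoseError, ValueError):
    """A structure mask selects no voxels."""


class EmptyResultError(EpidoseError, ValueError):
    """All voxels were excluded from an evaluation."""


class FormatError(EpidoseError, IOError):
    """Unrecognized or malformed file format."""


class MetadataError(EpidoseError, IOError):
    """Required metadata (spacing/origin) missing from a file."""


class StageError(EpidoseError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
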