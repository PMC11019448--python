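"""Exception hierarchy shared across the package."""


class ClixError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ClixError, ValueError):
    """Invalid input data (negative counts, NaN, malformed records...)."""


class ReferenceTooSmallError(ValidationError):
    """Too few complete cases to build a reference distribution."""


class ScoreRangeError(ValidationError):
    """A score outside the admissible [0, 40] range."""


class ConstantInputError(ValidationError):
    """A rank statistic is undefined because an input vector is constant."""


class InsufficientDataError(ClixError):
    """Not enough observations to compute the requested quantity."""


class SubgroupShortfallError(ClixError):
    """Fewer eligible cases than requested for a subtype subgroup.

    Carries the offending subtype so callers can report which stratum
    came up short.
    """

    def __init__(self, subtype: str, available: int, requested: int):
        self.subtype = subtype
        self.available = available
        self.requested = requested
        super().__init__(
            f"subtype {subtype}: only {available} eligible cases, "
            f"{requested} requested"
        )
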