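"""Exceptions and warnings shared across the package."""


class SchemaError(ValueError):
    """Invalid indicator schema or grade scheme (duplicate codes, gaps...)."""


class ScoreValidationError(ValueError):
    """Score matrix violates its contract (range, missing cells/columns)."""


class DegeneracyError(RuntimeError):
    """Scores carry no usable information (e.g. every entropy equals 1)."""


class AllZeroMembershipError(RuntimeError):
    """Every grade membership is zero; fall back to interval lookup."""


class DegeneracyWarning(UserWarning):
    """A degenerate but recoverable condition was handled.

    Emitted when a constant column is normalized to zeros, an all-zero
    normalized column is assigned maximal entropy, or a backward-cloud
    hyper-entropy is clamped to zero.
    """
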