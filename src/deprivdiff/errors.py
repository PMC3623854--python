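"""Exception hierarchy for the deprivdiff pipeline.

Every stage raises a subclass of :class:`DeprivDiffError` so callers can
distinguish pipeline failures from programming errors. Messages name the
offending field, column or area identifier wherever one exists.
"""


class DeprivDiffError(Exception):
    """Base class for all deprivdiff errors."""


class ConfigurationError(DeprivDiffError):
    """A configuration field is missing, out of range or inconsistent."""


class InputError(DeprivDiffError):
    """Input data violate a precondition (missing columns, unknown ids, ...)."""


class DegenerateInputError(DeprivDiffError):
    """Numerically degenerate input: constant vectors, collinear predictors,
    a near-zero denominator in a ratio."""
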