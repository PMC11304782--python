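"""Exception hierarchy.

All package errors derive from :class:`CopswayError` so callers can catch one
type at a pipeline boundary while tests can assert on the precise failure.
"""


class CopswayError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CopswayError, ValueError):
    """An on-disk artifact does not match the declared dialect (bad header,
    non-numeric body, unparseable metadata line)."""


class ValidationError(CopswayError, ValueError):
    """Well-formed input whose values violate a domain invariant
    (non-monotone time, unknown condition token, negative duration ...)."""


class DegenerateTrajectoryError(CopswayError, ValueError):
    """A trajectory carries no usable spatial information (all points
    identical), so no ellipse can be fitted."""
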