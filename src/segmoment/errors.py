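"""Exception hierarchy.

Every error carries a short machine-parsable ``code`` used by the CLI to
emit single-line diagnostics and exit non-zero.
"""


class SegmomentError(Exception):
    """Base class for all package errors."""

    code = "error"


class SingularAngleError(SegmomentError):
    """Rotation angle too close to 0 or 360 degrees: the CoM displacement
    vanishes and the estimator's noise amplification is unbounded."""

    code = "singular-angle"


class DegenerateGeometryError(SegmomentError):
    """Support points are (nearly) collinear; the statics system is rank
    deficient and the CoM is not identifiable."""

    code = "degenerate-geometry"


class EmptyLoadError(SegmomentError):
    """All three scale readings are zero."""

    code = "empty-load"


class TippingError(SegmomentError):
    """System CoM outside the support triangle: one support load would be
    negative, i.e. the board lifts off that support."""

    code = "tipping"


class InconsistentSessionError(SegmomentError):
    """The two states of a measurement pair disagree on the total supported
    mass beyond tolerance."""

    code = "inconsistent-session"


class SessionFormatError(SegmomentError):
    """Malformed session CSV or geometry/config JSON."""

    code = "session-format"


class ConfigError(SegmomentError):
    """Invalid run configuration (unknown keys, missing fields, bad types)."""

    code = "config"
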