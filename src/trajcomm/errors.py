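"""Exception hierarchy shared by all pipeline stages."""


class TrajcommError(Exception):
    """Base class for all package errors."""


class FormatError(TrajcommError):
    """Unparsable record in an input file; message names the offending line."""


class IntegrityError(TrajcommError):
    """Input violates a structural invariant (e.g. duplicate atom id)."""


class ShapeError(TrajcommError):
    """Atom/frame count mismatch between trajectory and structure."""


class EmptyInputError(TrajcommError):
    """Operation received zero frames / zero atoms."""


class SchemeError(TrajcommError):
    """Region scheme is missing a region or resolves to no atoms."""


class ArgumentError(TrajcommError):
    """Invalid argument value."""


class PreconditionError(TrajcommError):
    """A documented precondition does not hold (e.g. hydrogens absent)."""


class DegenerateError(TrajcommError):
    """Computation is degenerate (zero mode, all-zero spectrum, <3 fit atoms)."""


class InsufficientDataError(TrajcommError):
    """Not enough frames for the requested statistic."""


class StrideError(TrajcommError):
    """Requested stride is not commensurate with the frame spacing."""


class ConnectivityError(TrajcommError):
    """Contact graph is disconnected where connectivity is required."""


class ThresholdError(TrajcommError):
    """No usable threshold exists (e.g. degenerate commute-time matrix)."""


class ComparisonError(TrajcommError):
    """Two report bundles are not comparable (scheme mismatch)."""


class LabelingError(TrajcommError):
    """Quarter/half labels do not cover all frames."""
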