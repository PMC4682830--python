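"""Exception hierarchy.

Every contract violation raises a distinct, named error so callers can
discriminate bad labels from bad files from degenerate class structure.
"""


class DramoteError(Exception):
    """Base class for all package errors."""


class MissingLabelColumnError(DramoteError, KeyError):
    """The requested label column is absent from the CSV header."""


class NonNumericFeatureError(DramoteError, ValueError):
    """A feature cell failed to parse as a finite number."""


class LabelDomainError(DramoteError, ValueError):
    """A label value lies outside the bipolar {-1, +1} domain."""


class LengthMismatchError(DramoteError, ValueError):
    """Paired vectors (labels/predictions/scores) differ in length."""


class EmptyClassError(DramoteError, ValueError):
    """An operation requires both classes to be present."""


class InsufficientMinorityError(DramoteError, ValueError):
    """Interpolation-based oversampling needs at least two minority rows."""


class StratificationError(DramoteError, ValueError):
    """A class is too small for the requested number of stratified folds."""


class FeatureCountMismatchError(DramoteError, ValueError):
    """Candidate feature count differs from the training feature count."""


class MissingCellsError(DramoteError, ValueError):
    """A result table is incomplete for the requested aggregation."""


class CapabilityError(DramoteError, RuntimeError):
    """An optional runtime capability (e.g. a chemistry toolkit) is missing."""
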