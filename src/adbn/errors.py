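"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`AdbnError`,
so callers can catch pipeline failures with a single except clause while
tests can assert the precise failure mode.
"""


class AdbnError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AdbnError):
    """Input table is missing mandatory columns or violates the dictionary."""


class IntegrityError(AdbnError):
    """Row-level invariant violated (duplicate keys, out-of-range CDR...)."""


class FeatureLookupError(AdbnError, KeyError):
    """A named feature is not present in the data dictionary."""


class ValidationError(AdbnError, ValueError):
    """A configuration or simulation spec fails its invariants."""


class InputError(AdbnError, ValueError):
    """Operation-level precondition violated (length mismatch, bad argument)."""


class DegenerateIntervalError(AdbnError):
    """A discretization interval contains no observations."""


class DegenerateFeatureError(AdbnError):
    """Feature cannot be discretized (all values identical, single class...)."""


class OutOfSupportError(AdbnError):
    """A value falls outside a fixed scheme's declared categories."""


class UndefinedRatioError(AdbnError):
    """Entropy-ratio filter undefined (zero-entropy denominator)."""


class UndefinedCorrelationError(AdbnError):
    """Correlation undefined because one vector has zero variance."""


class InsufficientNeighborsError(AdbnError):
    """SMOTE requires at least two records in the minority class."""


class GraphError(AdbnError):
    """Directed graph is cyclic where a DAG is required."""


class ConstraintError(AdbnError):
    """Structure-learning constraints are mutually inconsistent."""


class StratificationError(AdbnError):
    """A stratum is too small to appear on both sides of a split."""
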