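"""Exception hierarchy for the revmr package.

All revmr-specific failures derive from :class:`RevmrError` so callers can
catch the package's errors with a single except clause while still
distinguishing, e.g., a malformed input file from an under-identified model.
"""


class RevmrError(Exception):
    """Base class for all revmr errors."""


class FormatError(RevmrError, ValueError):
    """An input file does not conform to the expected tabular dialect."""


class EmptyInputError(RevmrError, ValueError):
    """An operation received a table with no usable rows."""


class MissingLdError(RevmrError, KeyError):
    """A variant required for LD pruning is absent from the LD matrix."""


class InsufficientInstrumentsError(RevmrError, ValueError):
    """Too few instruments for the requested estimator."""


class DegenerateInstrumentError(RevmrError, ValueError):
    """A per-SNP ratio is undefined (zero exposure effect)."""


class CollinearityError(RevmrError, ValueError):
    """The multivariable design matrix is rank deficient."""


class ConfigError(RevmrError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class StateError(RevmrError, RuntimeError):
    """An operation was applied in an invalid state (e.g. double scaling)."""


class AlignmentError(RevmrError, ValueError):
    """Two result sets could not be aligned on a common key set."""


class MatrixError(RevmrError, ValueError):
    """A supplied matrix violates symmetry / PSD / unit-diagonal requirements."""


class ReportError(RevmrError, ValueError):
    """Required result tables are missing or unreadable for reporting."""
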