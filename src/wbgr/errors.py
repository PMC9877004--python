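"""Exception hierarchy for the wbgr package.

Every error raised by wbgr derives from :class:`WbgrError`, so callers can
catch the whole family with one clause.  Subclasses distinguish malformed
files (:class:`FormatError`), semantically invalid but well-formed inputs
(:class:`ValidationError`), bad analysis configuration, and degenerate data
situations.
"""


class WbgrError(Exception):
    """Base class for all wbgr errors."""


class FormatError(WbgrError):
    """An on-disk file does not conform to its expected format.

    Messages name the offending line, row or column so the file can be fixed.
    """


class ValidationError(WbgrError):
    """A well-formed input violates a domain invariant (duplicates, bad enum
    tokens, negative counts, out-of-range p-values, ...)."""


class ConfigurationError(WbgrError):
    """A simulation or analysis configuration parameter is out of range."""


class DesignError(WbgrError):
    """The sample design cannot support the requested comparison
    (missing group, aliased covariate, no control samples, ...)."""


class PairingError(WbgrError):
    """Pre/post sample pairing by donor is incomplete or ambiguous."""


class EstimationError(WbgrError):
    """A normalization or model quantity is undefined on the given data."""


class InsufficientDataError(WbgrError):
    """Too few observations to compute the requested statistic."""


class EmptyOutputError(WbgrError):
    """A filtering step removed everything; thresholds likely need review."""
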