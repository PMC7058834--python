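"""Exception hierarchy.

Every failure mode named in a module contract maps to a distinct class so
callers (and the CLI) can branch on machine-readable error types rather than
message text.
"""


class CpgmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CpgmrError):
    """A configuration problem, e.g. a missing mandatory column."""


class EmptyInputError(CpgmrError):
    """An input that must be nonempty was empty."""


class EmptyOverlapError(CpgmrError):
    """No SNP survives the exposure/outcome intersection."""


class WeakInstrumentError(CpgmrError):
    """Instrument with zero (or unusable) SNP-exposure effect."""


class DegenerateSampleError(CpgmrError):
    """Sample size too small for the requested statistic."""


class InsufficientInstrumentsError(CpgmrError):
    """Fewer SNPs than the estimator's minimum."""


class DegenerateDesignError(CpgmrError):
    """Design matrix without variation (e.g. constant exposure betas)."""


class SingularLDError(CpgmrError):
    """LD-weighted covariance matrix is singular."""


class CollinearExposuresError(CpgmrError):
    """Multivariable exposure matrix is rank deficient."""


class InvalidInstrumentSetError(CpgmrError):
    """Summed instrument r-squared reaches or exceeds 1."""


class RegionTooSmallError(CpgmrError):
    """Colocalization region with fewer than the minimum qualifying variants."""


class NoTestableGeneError(CpgmrError):
    """Every candidate gene region was filtered out."""


class EmptyStageError(CpgmrError):
    """A pipeline stage produced no testable results."""


class UnsupportedError(CpgmrError):
    """Request outside the supported range (e.g. >3 colocalization traits)."""
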