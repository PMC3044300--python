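"""Exception hierarchy for hdxstat.

All package-specific errors derive from :class:`HdxError` so callers can
catch one base class; per-peptide statistical failures raise the narrower
subclasses, which batch drivers log and skip rather than propagate.
"""


class HdxError(Exception):
    """Base class for all hdxstat errors."""


class FormatError(HdxError):
    """A tabular input does not conform to the expected dialect (bad header,
    unknown or missing column)."""


class ValidationError(HdxError):
    """A structurally well-formed input violates a domain invariant
    (nonpositive m/z, negative intensity, duplicate peaks, mixed charge)."""


class EmptyDatasetError(HdxError):
    """No peptide survived dataset assembly or filtering."""


class PairingError(HdxError):
    """The two comparison states cannot be paired on a common timepoint set."""


class InsufficientDataError(HdxError):
    """Too few observations or timepoints for the requested statistic."""


class MissingReferenceError(HdxError):
    """Percent-deuteration was requested but no nondeuterated/fully
    deuterated anchor (measured or theoretical) is available."""


class DegenerateClusterError(HdxError):
    """An isotopic cluster has zero total intensity, so no centroid exists."""


class DesignRankError(HdxError):
    """The regression design matrix is rank deficient (collinear terms)."""
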