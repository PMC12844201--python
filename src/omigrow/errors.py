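"""Exception hierarchy for omigrow.

Every error raised on bad user input derives from :class:`OmigrowError`
(itself a ``ValueError``) so callers can catch one base class.
"""


class OmigrowError(ValueError):
    """Base class for all omigrow input/contract errors."""


class InvalidDesignError(OmigrowError):
    """Condition design violates its invariants (too few conditions, no substrates...)."""


class InvalidTruthError(OmigrowError):
    """Planted-truth request is inconsistent (e.g. n_planted >= n_features)."""


class InputError(OmigrowError):
    """Generic malformed input: bad shapes, non-increasing timepoints, unknown IDs."""


class DegenerateCurveError(OmigrowError):
    """Growth curve cannot be fitted (flat OD trace, too few timepoints)."""


class IncompleteTargetsError(OmigrowError):
    """A growth-rate table was requested but some conditions lack a converged fit."""


class NoOverlapError(OmigrowError):
    """Layer matching found no gene/protein pairs shared by both matrices."""


class AlreadyStandardizedError(OmigrowError):
    """Standardization applied twice; refusing to double-scale."""


class MetricDomainError(OmigrowError):
    """Metric undefined on this input (e.g. relative accuracy with y <= 0)."""


class MappingError(OmigrowError):
    """Importance combination found features not covered by the gene/protein map."""


class InsufficientGroupError(OmigrowError):
    """Differential testing needs at least two conditions per oxygen group."""
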