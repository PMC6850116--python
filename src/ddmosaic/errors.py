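"""Exception hierarchy.

Every stage raises a stage-specific subclass of :class:`DDMosaicError` so
pipeline callers can name the failing stage without string matching.
"""


class DDMosaicError(Exception):
    """Base class for all package errors."""


class ParameterError(DDMosaicError, ValueError):
    """A parameter is non-finite, out of range, or otherwise invalid.

    The message always names the offending field.
    """


class GatingError(DDMosaicError, RuntimeError):
    """Droplet gating cannot proceed (too few droplets, degenerate input)."""


class EstimationError(DDMosaicError, RuntimeError):
    """MAF estimation is impossible (e.g. zero informative droplets).

    Distinct from an estimate of 0: no denominator means no estimate.
    """


class ClusteringError(DDMosaicError, RuntimeError):
    """Too few usable rows / invalid distance matrix for clustering."""


class FixtureError(DDMosaicError, KeyError):
    """Unknown packaged fixture name."""


class AmbiguousInheritanceError(DDMosaicError, RuntimeError):
    """Contradictory family data (e.g. both parents mosaic for one variant);

    flagged for manual review rather than silently classified.
    """


class PipelineError(DDMosaicError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
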