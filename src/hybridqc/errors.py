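"""Exception hierarchy for hybridqc.

All domain-rule violations derive from :class:`HybridQCError` so callers can
catch package errors without masking programming errors.
"""


class HybridQCError(Exception):
    """Base class for all hybridqc errors."""


class DomainError(HybridQCError, ValueError):
    """Input violates a physical or mathematical precondition."""


class GridError(HybridQCError, ValueError):
    """Abscissae of curves that must share a grid do not match."""


class ResolutionError(HybridQCError, ValueError):
    """Requested temporal feature is below the grid resolution."""


class DynamicRangeError(HybridQCError, RuntimeError):
    """DTOF dynamic range too low for a diffusion-model fit.

    Raised with the message ``insufficient dynamic range``: the histogram
    peak is less than one decade above the background, so the tail slope
    carrying the absorption information is not resolved.
    """


class InsufficientDecayError(HybridQCError, RuntimeError):
    """g2 carries no analyzable field-correlation decay.

    Raised with the message ``insufficient decay sampled`` when the coherence
    plateau is not resolvable (beta not estimable or below the floor) or when
    fewer than five leading points lie above the g1 fit cutoff.
    """


class EstimationError(HybridQCError, RuntimeError):
    """A required signal feature (e.g. the beta plateau) cannot be estimated."""


class UndefinedWidthError(HybridQCError, ValueError):
    """Curve has no two half-maximum crossings; FWHM undefined."""


class ConfigurationError(HybridQCError, ValueError):
    """Rule set, background window or config file is invalid."""


class SchemaError(HybridQCError, ValueError):
    """Dataset table or composition string violates the schema."""


class CurveFormatError(HybridQCError, ValueError):
    """Curve file or sidecar fails validation."""
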