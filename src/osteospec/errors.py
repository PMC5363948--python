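"""Exception hierarchy.

All osteospec errors derive from :class:`OsteospecError` so callers can
catch the package's failures with a single clause; subclasses distinguish
malformed files from scientific degeneracies (dead pixels, fully degraded
organic phases) that a pipeline may want to handle by substitution rather
than abort.
"""


class OsteospecError(Exception):
    """Base class for all osteospec exceptions."""


class FormatError(OsteospecError):
    """A cube container header is malformed or missing a required field."""


class IntegrityError(OsteospecError):
    """Declared shape and stored payload disagree."""


class ParameterError(OsteospecError, ValueError):
    """An argument violates a documented precondition."""


class SpectralDomainError(OsteospecError, ValueError):
    """A wavenumber window does not overlap the axis, or a selection is empty."""


class DegenerateSpectrumError(OsteospecError):
    """Zero-norm (dead-pixel) spectrum where a norm is required."""


class SuspiciousSpectrumError(OsteospecError):
    """Despiking would alter more channels than plausible for cosmic rays."""


class PackingError(OsteospecError):
    """Osteon discs could not be placed without overlap."""


class DegenerateRatioError(OsteospecError):
    """Ratio denominator is non-positive (fully degraded organic phase)."""


class SelectionError(OsteospecError):
    """Too few eligible pixels for the requested ROI selection."""
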