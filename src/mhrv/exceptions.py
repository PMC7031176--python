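"""Exception hierarchy for mhrv.

All errors raised by the library derive from :class:`MhrvError` so callers
can catch a single base class at pipeline level.
"""


class MhrvError(Exception):
    """Base class for all mhrv errors."""


class ParseError(MhrvError):
    """Malformed input file (bad header, non-monotonic times, ...)."""


class EmptyInputError(ParseError):
    """Input file contains no data rows."""


class ValidationError(MhrvError):
    """Semantic validation failure (manifest levels, scheme ordering, ...)."""


class ConfigurationError(MhrvError):
    """Inconsistent analysis configuration (band above Nyquist, ...)."""


class InsufficientDataError(MhrvError):
    """Series too short for the requested statistic."""


class DegenerateInputError(MhrvError):
    """Input has no usable variation (constant series, zero tolerance)."""


class NoPeaksError(MhrvError):
    """R-peak detection found nothing usable (flat signal)."""


class CleaningError(MhrvError):
    """Artifact cleaning would discard an unacceptable fraction of beats."""


class GenerationError(MhrvError):
    """Synthetic generation produced an invalid state (non-positive NN)."""


class EmptyDeltaError(MhrvError):
    """No complete basal/intrinsic pairs available for a delta summary."""
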