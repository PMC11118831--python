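"""Exception hierarchy for the eegmixer pipeline."""


class EegMixerError(Exception):
    """Base class for all package-specific errors."""


class MontageError(EegMixerError, ValueError):
    """Channel labels do not form a valid 10-20 montage."""


class FilterError(EegMixerError, ValueError):
    """Invalid band-pass filter parameters or too-short input."""


class SegmentationError(EegMixerError, ValueError):
    """Recording too short to yield a single epoch."""


class FormatError(EegMixerError, ValueError):
    """A recording file could not be parsed."""


class SplitError(EegMixerError, ValueError):
    """Too few subjects for the requested subject-disjoint split."""


class ConfigError(EegMixerError, ValueError):
    """Inconsistent model or training configuration."""
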