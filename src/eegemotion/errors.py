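"""Exception hierarchy shared across the package."""


class EEGEmotionError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EEGEmotionError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(EEGEmotionError, ValueError):
    """A data file does not have the expected layout."""


class DataUnavailableError(EEGEmotionError, FileNotFoundError):
    """A requested data file does not exist."""


class FilterDesignError(EEGEmotionError, ValueError):
    """A digital filter design is numerically unstable."""


class SegmentationOverflowError(EEGEmotionError, ValueError):
    """A segmentation request does not fit inside the recording."""
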