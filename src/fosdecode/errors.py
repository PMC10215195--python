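"""Exception hierarchy shared across the pipeline stages."""


class FosDecodeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FosDecodeError, ValueError):
    """A parameter or configuration value violates its contract."""


class DataError(FosDecodeError, ValueError):
    """Recorded data violate an invariant (shape, positivity, metadata)."""


class SegmentationError(FosDecodeError, ValueError):
    """Trials or analysis windows cannot be formed as requested."""


class FeatureError(FosDecodeError, ValueError):
    """Wavelet-coherence features are undefined for the given input."""


class DecodeError(FosDecodeError, ValueError):
    """Cross-validation or classification cannot proceed."""


class BlockIOError(FosDecodeError, IOError):
    """A recording container is missing arrays or metadata."""
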