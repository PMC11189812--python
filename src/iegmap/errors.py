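"""Exception types shared across the package."""


class IegmapError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IegmapError):
    """A simulation or pipeline configuration is internally inconsistent."""


class FormatError(IegmapError):
    """An input file violates its declared CSV dialect."""


class DegenerateInputError(IegmapError):
    """Input is structurally valid but statistically degenerate
    (zero-variance region, zero baseline SD, rank-deficient covariance)."""


class EventValidationError(IegmapError):
    """An event log violates ordering or non-overlap requirements."""
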