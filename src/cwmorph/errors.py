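"""Exception hierarchy for cwmorph."""


class CwmorphError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CwmorphError, ValueError):
    """A parameter value violates its documented constraints."""


class FormatError(CwmorphError, ValueError):
    """A data file does not conform to the expected dialect."""


class MissingLandmarkError(CwmorphError, ValueError):
    """An operation that requires complete configurations met missing landmarks."""


class DetectionError(CwmorphError, RuntimeError):
    """Breath endpoint detection failed (constant, too short or degenerate signal)."""


class DegenerateSampleError(CwmorphError, ValueError):
    """A statistical test received a degenerate sample (e.g. all zero differences)."""
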