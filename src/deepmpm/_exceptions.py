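"""Exception hierarchy shared across the package."""


class DeepMPMError(Exception):
    """Base class for all package errors."""


class InputError(DeepMPMError):
    """Invalid user-supplied data (shapes, ranges, empty selections)."""


class ConfigError(DeepMPMError):
    """Invalid or ambiguous configuration (unknown keys, missing metadata)."""


class DegenerateInputError(InputError):
    """Input is formally valid but degenerate for the requested analysis,
    e.g. a constant image passed to an auto-thresholder."""


class BleachCorrectionError(DeepMPMError):
    """A bleach-reference frame has non-positive background-subtracted signal."""


class FitError(DeepMPMError):
    """A regression failed to converge or had too few usable points."""


class AnalysisError(DeepMPMError):
    """A pipeline stage produced no usable output (e.g. empty threshold mask)."""
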