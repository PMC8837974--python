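"""Exception hierarchy shared by all pipeline stages."""


class BulbarVoiceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BulbarVoiceError, ValueError):
    """A configuration value is inconsistent with the input (e.g. non-divisible rate)."""


class InputError(BulbarVoiceError, ValueError):
    """The input data cannot be processed (empty, too short, wrong shape)."""


class DegenerateInputError(BulbarVoiceError, ValueError):
    """The input is formally valid but degenerate (constant signal, zero variance)."""


class UnvoicedSegmentError(BulbarVoiceError, RuntimeError):
    """No voiced frames were found in a segment.

    Carries per-frame diagnostics in ``diagnostics`` to aid debugging.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class InsufficientCyclesError(BulbarVoiceError, RuntimeError):
    """Fewer glottal cycles were detected than the requested measure needs."""
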