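"""Package-specific exceptions."""


class AvmsiError(Exception):
    """Base class for errors raised by avmsi."""


class DegenerateSignalError(AvmsiError):
    """A correlation or z-score was requested on a (near-)constant signal."""


class SingularSystemError(AvmsiError):
    """The regularized normal equations are singular (raise the ridge parameter)."""


class UnusableRecordingError(AvmsiError):
    """Every channel of a recording was flagged as bad."""
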