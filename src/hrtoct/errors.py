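"""Exception hierarchy shared by all hrtoct modules."""


class HrtOctError(Exception):
    """Base class for all errors raised by hrtoct."""


class InvalidInputError(HrtOctError, ValueError):
    """An input violates a documented precondition or invariant."""


class DegenerateSignalError(HrtOctError):
    """A signal is degenerate (e.g. identically zero) and cannot be analysed."""


class RegistrationError(HrtOctError):
    """Rigid registration cannot proceed (e.g. all-zero reference image)."""
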