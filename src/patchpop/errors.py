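"""Exception types shared across the package."""


class PatchpopError(Exception):
    """Base class for package errors."""


class InvalidProtocolError(PatchpopError, ValueError):
    """Raised when a stimulation protocol is malformed (non-positive rate, duration...)."""


class InvalidDesignError(PatchpopError, ValueError):
    """Raised when a population design is malformed (negative rates, overlapping events)."""


class InsufficientDataError(PatchpopError, ValueError):
    """Raised when a trace or table is too short/small for the requested measurement."""


class SingularFitError(PatchpopError, ValueError):
    """Raised when a regression problem is degenerate (e.g. identical step amplitudes)."""
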