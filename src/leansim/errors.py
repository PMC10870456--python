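"""Exception hierarchy for the leansim pipeline.

Every stage raises a subclass of :class:`LeanSimError` so the CLI can map
failures to categorized exit codes (config errors -> 2, stage errors -> 1).
"""


class LeanSimError(Exception):
    """Base class for all leansim errors."""


class ValidationError(LeanSimError, ValueError):
    """An input value violates a documented precondition or invariant."""


class ConfigError(LeanSimError):
    """A run configuration file is malformed or fails schema validation."""


class FormatError(LeanSimError):
    """A trial file or table does not conform to the documented format."""


class SimulationDivergedError(LeanSimError):
    """The closed loop left the small-angle regime (|theta| above the cap)."""

    def __init__(self, message, k_p=None, k_ff=None, t=None):
        super().__init__(message)
        self.k_p = k_p
        self.k_ff = k_ff
        self.t = t


class NoAPADetectedError(LeanSimError):
    """No sustained threshold crossing opposite the target was found."""


class SegmentationFailedError(LeanSimError):
    """The COP signal lacks the expected phase structure (e.g. no peak)."""


class IdentificationInfeasibleError(LeanSimError):
    """No closed-loop-stable starting point exists within the gain bounds."""
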