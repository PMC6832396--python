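"""Exception hierarchy shared across the package."""


class HandpilotError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(HandpilotError):
    """A calibration recording is unusable (e.g. contraction not clearly
    visible above rest, or a movement class has too few examples)."""


class ScriptError(HandpilotError):
    """A scripted session violates its timing constraints."""


class ConfigError(HandpilotError):
    """A configuration object is incomplete or inconsistent."""


class FormatError(HandpilotError):
    """A persisted file cannot be parsed or has an unsupported version."""
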