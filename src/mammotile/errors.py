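"""Exception hierarchy shared across the package."""


class MammotileError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(MammotileError):
    """Invalid box, frame, or tile-plan geometry."""


class InvalidFrameError(GeometryError):
    """A coordinate frame with a non-positive scale or negative offset."""


class GenerationError(MammotileError):
    """Phantom synthesis failed (e.g. lesion placement exhausted retries)."""


class PreprocessingError(MammotileError):
    """Foreground extraction produced no usable breast region."""


class ConfigError(MammotileError):
    """Inconsistent or unknown configuration value."""


class InputError(MammotileError):
    """Malformed external input (CSV/JSON schema violations, id mismatches)."""
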