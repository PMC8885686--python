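"""Exception hierarchy shared across the package."""


class RaretaxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RaretaxError):
    """A file or in-memory representation violates the expected format."""


class ParameterError(RaretaxError, ValueError):
    """A caller-supplied parameter is outside its valid range."""


class ConsistencyError(RaretaxError):
    """Two objects that must describe the same entities do not agree."""


class ComputationError(RaretaxError):
    """A quantity is undefined for the given input (e.g. an empty sample)."""


class StageError(RaretaxError):
    """A pipeline stage failed; the message names the stage."""
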