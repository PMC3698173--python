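"""Exception hierarchy for invalid parameters, geometry and configuration."""


class AsterDragError(Exception):
    """Base class for all package errors."""


class ParameterError(AsterDragError, ValueError):
    """A physical parameter violates its invariant (names the offending field)."""


class GeometryError(AsterDragError, ValueError):
    """The embryo geometry or a position query is inconsistent."""


class ModelError(AsterDragError, ValueError):
    """The model state cannot be evolved (e.g. empty microtubule array)."""


class ConfigError(AsterDragError, ValueError):
    """A run configuration file is malformed or contains unknown/invalid keys."""
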