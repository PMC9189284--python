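"""Exception hierarchy shared by all pipeline stages."""


class ScMarkersError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ScMarkersError):
    """A parameter or configuration value is outside its documented domain."""


class ValidationError(ScMarkersError):
    """Input data violates an invariant (negative values, missing labels, ...)."""


class FormatError(ScMarkersError):
    """An on-disk artifact is malformed (duplicate ids, bad header, ...)."""


class ConsistencyError(ScMarkersError):
    """Two artifacts that must agree (matrix vs. result, rules vs. cells) do not."""
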