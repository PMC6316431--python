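"""Exception hierarchy shared across the package."""


class SomaqcError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(SomaqcError):
    """File or dataset structure is invalid (duplicate keys, missing columns,
    dimension mismatches). The message names the offending key or location."""


class DataValueError(SomaqcError):
    """A cell value violates an invariant (nonpositive RFU, non-numeric text).
    The message carries row/column coordinates."""


class ConfigError(SomaqcError):
    """A configuration value is invalid or a required group is too small."""


class OrderingError(SomaqcError):
    """A pipeline stage was invoked before its prerequisite stage."""
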