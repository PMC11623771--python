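"""Exception taxonomy shared across the package."""


class MemdecodeError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(MemdecodeError, ValueError):
    """Invalid configuration values (fractions out of range, bad windows, ...)."""


class FormatError(MemdecodeError, ValueError):
    """Malformed input file (missing columns, unparseable values)."""


class DimensionError(MemdecodeError, ValueError):
    """Mismatched array shapes / grids between coupled objects."""


class CoverageError(MemdecodeError, ValueError):
    """Requested time window not covered by the available recording span."""


class DegenerateFoldError(MemdecodeError, RuntimeError):
    """A training subset contains a single class and cannot be fit."""
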