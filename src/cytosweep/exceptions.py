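"""Exception types shared across the package."""


class CytosweepError(Exception):
    """Base class for all package errors."""


class FormatError(CytosweepError, ValueError):
    """A file could not be parsed in the named format."""


class DimensionError(CytosweepError, ValueError):
    """Mismatched array/table dimensions."""


class EmptyInputError(CytosweepError, ValueError):
    """No usable events remain after loading/filtering."""


class ParameterError(CytosweepError, ValueError):
    """An invalid configuration parameter."""
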