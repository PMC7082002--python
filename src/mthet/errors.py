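"""Exception types shared across modules."""


class MthetError(Exception):
    """Base class for all package errors."""


class SchemaError(MthetError, ValueError):
    """Malformed tabular input; message carries the offending row number."""


class NoSignalError(MthetError, ValueError):
    """All peak heights at a site are zero."""


class InsufficientDataError(MthetError, ValueError):
    """Too few usable records to run an analysis."""


class DegenerateInputError(MthetError, ValueError):
    """Input lies on the boundary of the parameter space (e.g. mean fraction 0 or 1)."""


class ConfigurationError(MthetError, ValueError):
    """Inconsistent simulation or run configuration."""


class LengthMismatchError(MthetError, ValueError):
    """Sequences expected to be aligned have unequal lengths."""
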