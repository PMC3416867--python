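"""Exception types shared across the pipeline."""


class ChromastressError(Exception):
    """Base class for all package errors."""


class ConfigError(ChromastressError):
    """Invalid simulation or analysis configuration; message names the field."""


class MissingReferenceError(ChromastressError):
    """No wild-type reference sample exists for a requested time point."""


class EstimationError(ChromastressError):
    """A fit or parameter estimate could not be computed from the given data."""
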