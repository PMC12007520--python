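"""Error types distinguishing bad configuration from bad data."""


class AslQuantError(Exception):
    """Base class for all aslquant errors."""


class ConfigurationError(AslQuantError):
    """Inconsistent or impossible analysis options (user-fixable)."""


class DataError(AslQuantError):
    """The input data violate a precondition (non-finite values, shape mismatch...)."""
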