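"""Exception hierarchy."""


class AgewireError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AgewireError):
    """An invalid configuration value; the message names the offending field."""


class InputError(AgewireError):
    """Malformed or inconsistent input data."""
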