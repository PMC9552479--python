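"""Package exception types."""


class PituiseqError(Exception):
    """Base class for package errors."""


class ConfigError(PituiseqError):
    """Invalid configuration value; message names the offending field."""


class InputError(PituiseqError):
    """Invalid or inconsistent input data."""


class FormatError(PituiseqError):
    """Malformed file or record."""
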