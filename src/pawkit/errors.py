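"""Exception hierarchy for pawkit."""


class PawkitError(Exception):
    """Base class for all pawkit errors."""


class FormatError(PawkitError):
    """A file could not be read or did not match the expected layout."""


class ParseError(FormatError):
    """A cell or row could not be parsed; message carries the row index."""


class ConfigError(PawkitError):
    """A run configuration value is invalid or inconsistent with the data."""


class ValidationError(PawkitError):
    """Data violated an invariant (e.g. likelihoods outside [0, 1])."""
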