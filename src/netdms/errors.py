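"""Exception hierarchy shared across the package.

CLI exit-code mapping: ConfigError -> 2, FormatError/ValidationError -> 3,
NumericalError -> 4.
"""


class NetdmsError(Exception):
    """Base class for all netdms errors."""


class FormatError(NetdmsError):
    """A file does not conform to its expected dialect."""


class ValidationError(NetdmsError):
    """Well-formed input that violates a semantic constraint."""


class ConfigError(NetdmsError):
    """Invalid or incomplete run configuration."""


class NumericalError(NetdmsError):
    """A numerical procedure failed (non-PSD matrix, degenerate fit, ...)."""
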