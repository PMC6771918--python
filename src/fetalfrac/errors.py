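"""Exception hierarchy shared across the package."""


class FetalFracError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FetalFracError):
    """Invalid configuration: bad grid parameters, infeasible simulation params."""


class FormatError(FetalFracError):
    """Malformed input file; the message names the offending line where possible."""


class ModelError(FetalFracError):
    """A model is degenerate, unfitted, or incompatible with the given input."""
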