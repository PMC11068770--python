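"""Exception types shared across the package."""


class MetaGwasError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MetaGwasError, ValueError):
    """A simulation or analysis configuration violates a stated bound."""


class DataFormatError(MetaGwasError, ValueError):
    """An input file or table is malformed (bad token, duplicate id, ...)."""


class ModelError(MetaGwasError, ValueError):
    """A statistical model cannot be fitted on the given input."""
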