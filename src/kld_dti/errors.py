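"""Exception hierarchy shared across the pipeline stages."""


class KldDtiError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(KldDtiError, ValueError):
    """A parameter or spec value is outside its documented range."""


class SchemaError(KldDtiError, ValueError):
    """An input table is missing a required column."""


class InputError(KldDtiError, ValueError):
    """An input is empty or unusable after filtering."""


class GridMismatchError(KldDtiError, ValueError):
    """Two density profiles do not share an evaluation grid."""
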