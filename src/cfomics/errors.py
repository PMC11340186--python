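"""Exception hierarchy shared across the pipeline."""


class CfomicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CfomicsError, ValueError):
    """A configuration value violates its contract; message names the field."""


class DataError(CfomicsError, ValueError):
    """An input table violates its schema or invariants."""
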