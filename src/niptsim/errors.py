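"""Exception types shared across the package."""


class NiptsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NiptsimError, ValueError):
    """A parameter object or config file violates its invariants."""


class DegeneratePanelError(NiptsimError, ValueError):
    """Reference panel cannot be built (too few samples or zero SD)."""


class SchemaError(NiptsimError, ValueError):
    """A tabular input does not match the expected column schema."""
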