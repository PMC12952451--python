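"""Exception hierarchy shared across the pipeline stages."""


class HccnetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HccnetError):
    """An input table is missing a mandatory column or field."""


class FormatError(HccnetError):
    """An input file violates its format contract (bad score, bad row)."""


class DataError(HccnetError):
    """Input values are structurally valid but semantically inconsistent."""


class ConfigurationError(HccnetError):
    """A parameter or panel/catalog configuration is unusable."""


class ContractError(HccnetError):
    """A precondition of an internal stage was violated by the caller."""
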