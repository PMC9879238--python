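"""Exception hierarchy shared across the pipeline."""


class OmixnetError(Exception):
    """Base class for all package errors."""


class FormatError(OmixnetError):
    """Malformed input file (duplicate ids, non-numeric cells, ...)."""


class ConfigError(OmixnetError):
    """Invalid configuration or simulation spec."""


class PipelineOrderError(OmixnetError):
    """A preprocessing operation was called out of order."""


class AnalysisError(OmixnetError):
    """A statistical operation received data it cannot handle."""
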