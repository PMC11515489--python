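"""Exception hierarchy shared across the pipeline stages."""


class OmicspredError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(OmicspredError):
    """Invalid configuration (bad field values, missing inputs, inconsistent specs)."""


class DegenerateInputError(OmicspredError):
    """Input has no usable structure (e.g. all-identical rows given to clustering)."""


class UndefinedMetricError(OmicspredError):
    """A performance metric is undefined on the given data (no usable pairs / one class)."""


class FoldWithoutEventError(OmicspredError):
    """A cross-validation fold contains no events, so the survival criterion is undefined."""


class SeparationError(OmicspredError):
    """Unpenalized logistic fit diverged on perfectly separable data."""
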