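"""Exception hierarchy shared across the pipeline."""


class MrsdatError(Exception):
    """Base class for all package errors."""


class ConfigError(MrsdatError):
    """A configuration file (recommendations, FFQ schema, bounds) is invalid."""


class UnsupportedAgeError(MrsdatError):
    """Age falls outside the range covered by the age/life-stage taxonomy."""


class SchemaError(MrsdatError):
    """Input data do not conform to the declared schema."""


class MissingDataError(MrsdatError):
    """A required response or intake component is absent."""


class DegenerateInputError(MrsdatError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
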