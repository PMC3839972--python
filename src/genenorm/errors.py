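"""Exception hierarchy."""


class GeneNormError(Exception):
    """Base class for all package errors."""


class CorpusParseError(GeneNormError):
    """Malformed BioC XML; message carries the reported byte/line position."""


class ValidationError(GeneNormError):
    """Document, annotation or evaluation input violates an invariant."""


class SchemaError(GeneNormError):
    """A tabular resource is missing a required column."""


class ParameterError(GeneNormError, ValueError):
    """A numeric parameter is outside its legal range."""


class ConfigError(GeneNormError):
    """Inconsistent generator/pipeline/weight configuration."""


class InfeasibleError(GeneNormError):
    """Hard constraints of a ground network cannot all be satisfied."""


class TrainingError(GeneNormError):
    """Weight learning was asked to run without usable gold annotations."""
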