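"""Exception hierarchy for the DDI extraction pipeline."""


class DDIError(Exception):
    """Base class for all pipeline errors."""


class CorpusParseError(DDIError):
    """Malformed corpus file (XML or CoNLL-U)."""


class CorpusValidationError(DDIError):
    """Structurally valid file with inconsistent content (e.g. dangling entity ids)."""


class AlignmentError(DDIError):
    """Dependency parse tokens do not align with the tokenized sentence."""


class TreeError(DDIError):
    """Dependency heads do not form a single-rooted tree."""


class ConfigError(DDIError):
    """Invalid configuration value."""


class ContractError(DDIError):
    """An operation was called with inputs violating its preconditions."""


class TrainingDivergence(DDIError):
    """Loss became non-finite during optimization."""
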