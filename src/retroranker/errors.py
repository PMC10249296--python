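"""Exception hierarchy shared across the package."""


class RetroRankerError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(RetroRankerError):
    """A SMILES or reaction SMILES string could not be parsed."""


class MappingError(RetroRankerError):
    """The atom map of a reaction is inconsistent or missing."""


class FormatError(RetroRankerError):
    """A prediction/label file violates the documented format."""


class UsageError(RetroRankerError):
    """An operation was called with invalid arguments."""


class SchemaError(RetroRankerError):
    """A feature schema does not match the one a model was trained with."""


class GenerationError(RetroRankerError):
    """The synthetic generator exhausted its retry budget."""


class SkipSignal(RetroRankerError):
    """Internal: a perturbation operator cannot apply to this record."""
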