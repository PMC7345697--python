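"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`QsrrError`, so callers (and the CLI) can distinguish domain
failures from genuine bugs.
"""


class QsrrError(Exception):
    """Base class for all qsrrkit errors."""


class FormatError(QsrrError):
    """An input file does not have the expected structure (missing columns, bad header)."""


class ValidationError(QsrrError):
    """Structurally valid input carries values that violate a contract
    (duplicate names, missing retention times, unknown descriptor columns, ...)."""


class DescriptorError(QsrrError):
    """Descriptor calculation failed for every compound."""


class InsufficientDataError(QsrrError):
    """Too few rows for the requested operation (training, CV, evaluation)."""


class DegenerateTargetError(QsrrError):
    """The retention-time target is constant; no model can be scored."""


class UndefinedStatisticError(QsrrError):
    """A statistic (t-test, regression fit) is undefined on this input."""


class ModelPersistenceError(QsrrError):
    """Base for model save/load failures."""


class CorruptModelError(ModelPersistenceError):
    """A model bundle file could not be deserialised."""


class IncompatibleModelError(ModelPersistenceError):
    """A model bundle has a format version this package cannot read."""
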