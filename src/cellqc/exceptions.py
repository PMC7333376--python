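"""Exception hierarchy shared across the workflow."""


class CellQCError(Exception):
    """Base class for all cellqc errors."""


class InputFormatError(CellQCError):
    """An input table or file violates the documented format contract."""


class EmptyInputError(InputFormatError):
    """No usable rows remain after ingestion/cleaning."""


class ParameterError(CellQCError):
    """A parameter is outside its valid range for the given data."""


class SchemaError(CellQCError):
    """Column/descriptor names do not match what a fitted model expects."""


class StateError(CellQCError):
    """An operation was called on an object in the wrong state."""


class ModelPersistenceError(CellQCError):
    """A persisted model file is corrupted or schema-incompatible."""


class VerdictError(CellQCError):
    """Phenotype verdicts are missing, incomplete, or inconsistent."""
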