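"""Exception types shared across the package."""


class TacticalSpaceError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(TacticalSpaceError):
    """Pitch dimensions or partition parameters are not physically valid."""


class ConfigurationError(TacticalSpaceError):
    """A run or simulation configuration is inconsistent."""


class InsufficientDataError(TacticalSpaceError):
    """Too few observations to perform the requested computation."""


class EncodingError(TacticalSpaceError):
    """A value could not be mapped into the category scheme."""


class UnknownPlayerError(TacticalSpaceError):
    """A requested player id is absent from the supplied tracks."""


class InvalidStateError(TacticalSpaceError):
    """A configuration vector violates the 4-hot invariant."""


class UndefinedEffectError(TacticalSpaceError):
    """An effect size is undefined (e.g. zero pooled standard deviation)."""


class SchemaError(TacticalSpaceError):
    """An input file violates the expected schema; message names column/line."""


class PipelineStageError(TacticalSpaceError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
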