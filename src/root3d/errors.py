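"""Exception types shared across the pipeline."""


class Root3DError(Exception):
    """Base class for all root3d errors."""


class CloudFormatError(Root3DError):
    """A point-cloud file could not be parsed in the requested dialect."""


class EmptyCloudError(Root3DError):
    """An operation received a cloud with no points."""


class MissingColorError(Root3DError):
    """A color-based operation was applied to a cloud without colors."""


class ParameterError(Root3DError):
    """An operation parameter violates its precondition."""


class GridSizeError(Root3DError):
    """A requested voxel lattice would exceed the hard cell-count cap."""


class PipelineStageError(Root3DError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
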