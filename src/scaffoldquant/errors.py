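"""Exception hierarchy for the scaffold quantification pipeline."""


class ScaffoldQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ScaffoldQuantError):
    """A parameter, option, or pipeline configuration is invalid."""


class DataQualityError(ScaffoldQuantError):
    """Input data violates a quality precondition (e.g., non-finite voxels)."""


class FormatError(ScaffoldQuantError):
    """An input file does not match the expected on-disk format."""


class PlacementError(ScaffoldQuantError):
    """The simulator could not place the requested cells in the volume."""

    def __init__(self, cell_class: str, placed: int, requested: int):
        self.cell_class = cell_class
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could not place {cell_class!r} cell {placed + 1} of {requested} "
            f"without overlap; reduce counts, radii, or enlarge the volume"
        )


class DegenerateDistributionError(ScaffoldQuantError):
    """All intensity values identical: normalization/thresholding undefined."""


class DesignError(ScaffoldQuantError):
    """A statistical or assay design cannot be applied to the given data."""


class AlignmentError(ScaffoldQuantError):
    """Kinetic traces do not share a common time grid."""


class PipelineStageError(ScaffoldQuantError):
    """A pipeline stage failed; wraps the underlying error with the stage name."""

    def __init__(self, stage: str, error: Exception):
        self.stage = stage
        self.error = error
        super().__init__(f"pipeline stage {stage!r} failed: {error}")
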