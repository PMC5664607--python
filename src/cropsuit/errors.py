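"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`CropsuitError` so callers (and the
CLI) can distinguish validation problems (exit code 2) from runtime failures.
"""


class CropsuitError(Exception):
    """Base class for all package errors."""


class InvalidRasterError(CropsuitError):
    """A raster violates a structural invariant (e.g. non-positive cell size)."""


class AlignmentError(CropsuitError):
    """Rasters combined in one analysis do not share shape/cell size/origin."""


class EmptyZoneError(CropsuitError):
    """A zonal operation was asked to summarise a zone with no valid cells."""


class ArgumentError(CropsuitError, ValueError):
    """A scalar argument is out of its documented domain."""


class ScoringError(CropsuitError):
    """A food record is missing a nutrient needed by the density score."""


class SelectionError(CropsuitError):
    """A scored food lacks the consumption/production series needed to screen it."""


class DegenerateSeriesError(CropsuitError):
    """An annual series cannot support a slope fit (all years identical)."""


class DegenerateDataError(CropsuitError):
    """Aggregate input data is degenerate (e.g. zero national acreage)."""


class EmptyCropError(CropsuitError):
    """A land-use layer contains no cells of the requested crop code."""


class ConfigurationError(CropsuitError):
    """A configuration value violates its schema (e.g. loss fraction >= 1)."""


class ReportError(CropsuitError):
    """A report table is structurally incomplete (missing crop x buffer cell)."""


class GenerationError(CropsuitError):
    """A synthetic-data design is infeasible on the requested grid."""


class PipelineError(CropsuitError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
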