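"""Exception types shared across the package."""


class OCTAError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(OCTAError, ValueError):
    """Scan geometry inconsistent with the data (file size, shape, pitches)."""


class FormatError(OCTAError, ValueError):
    """Unsupported on-disk format or dtype."""


class ConfigError(OCTAError, ValueError):
    """Invalid parameter or configuration value."""


class FractionError(OCTAError, RuntimeError):
    """A target vessel fraction could not be realized."""


class SegmentationError(OCTAError, RuntimeError):
    """Retinal surface segmentation failed (no detectable band)."""


class DegenerateHistogramError(OCTAError, ValueError):
    """Histogram thresholding is undefined (constant image/volume)."""


class ReportError(OCTAError, ValueError):
    """A cohort report could not be built (missing group or covariate)."""


class PipelineStageError(OCTAError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
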