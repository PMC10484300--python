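"""Exception hierarchy for the headcast pipeline."""


class HeadcastError(Exception):
    """Base class for all headcast errors."""


class InvalidConfigError(HeadcastError):
    """A configuration value violates its contract (non-positive spacing, overlapping grades...)."""


class MissingDataError(HeadcastError):
    """A requested date window is not covered by the available temperature series."""


class InvalidDataError(HeadcastError):
    """Input observations violate a precondition (e.g. non-positive head diameters)."""


class FitError(HeadcastError):
    """Nonlinear regression failed to converge or is under-determined."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DomainError(HeadcastError):
    """A head diameter lies outside the invertible domain of the growth curve."""


class DegenerateGeometryError(HeadcastError):
    """A polygon is degenerate (collinear vertices, zero area)."""


class ProjectionError(HeadcastError):
    """A point maps to (or near) the line at infinity under a homography."""


class DegenerateLayoutError(HeadcastError):
    """Ridge detection found no peak in the across-ridge position distribution."""


class EmptyWindowError(HeadcastError):
    """A requested crop window lies entirely outside the image extent."""


class UndefinedMetricError(HeadcastError):
    """An agreement metric is undefined (too few pairs, zero predictor variance)."""


class PipelineError(HeadcastError):
    """A pipeline stage is missing an upstream artifact; names the producing command."""
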