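"""Exception hierarchy for the simulation/segmentation pipeline."""


class SpectSegError(Exception):
    """Base class for all pipeline-specific errors."""


class SizingError(SpectSegError):
    """Requested phantom volume cannot be realised on the given grid."""


class PlacementError(SpectSegError):
    """A hotspot region cannot be placed as requested."""


class ConsistencyError(SpectSegError):
    """Case specification and phantom disagree (e.g. hotspot contrast without a hotspot region)."""


class CalibrationError(SpectSegError):
    """Noise calibration target unreachable within the search bracket."""


class RoiError(SpectSegError):
    """Automatic ROI derivation failed (no separable gland signal)."""


class PreprocessingError(SpectSegError):
    """Pre-processing produced a degenerate image (e.g. background exceeds gland signal)."""


class DegenerateHistogramError(SpectSegError):
    """Histogram has fewer than two occupied bins; no threshold exists."""


class MaskCollapseError(SpectSegError):
    """Chan-Vese mask collapsed to the empty or full volume."""

    def __init__(self, message: str, k: float | None = None):
        super().__init__(message)
        self.k = k


class SelectionError(SpectSegError):
    """Automatic k selection failed for every candidate."""


class ConfigurationError(SpectSegError):
    """Invalid benchmark configuration."""
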