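"""Exception hierarchy for the kinhet pipeline."""


class KinhetError(Exception):
    """Base class for all kinhet errors."""


class InvalidParameterError(KinhetError, ValueError):
    """A configuration or model parameter violates its contract."""


class GeometryError(KinhetError, ValueError):
    """Image/mask geometry mismatch (shape, spacing, or orientation)."""


class NormalizationError(KinhetError, ValueError):
    """Intensity normalization is undefined (empty or constant reference)."""


class SegmentationError(KinhetError, ValueError):
    """Subregion segmentation cannot proceed (e.g. empty tumor mask)."""


class UndefinedProfileError(KinhetError, ValueError):
    """Kinetic profile undefined: the tumor has no enhancing voxels."""


class DegenerateRoiError(KinhetError, ValueError):
    """ROI too small for reliable feature extraction; patient is flagged."""


class ScreeningError(KinhetError, ValueError):
    """Feature screening removed every feature."""


class ModelError(KinhetError, ValueError):
    """Model fitting or evaluation is undefined for the given inputs."""
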