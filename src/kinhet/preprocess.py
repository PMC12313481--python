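"""Geometry and intensity standardization for DCE-MRI series.

A :class:`DceSeries` is an ordered stack of co-registered 3-D volumes:
index 0 is the pre-contrast acquisition (S0), index 1 the first
post-contrast phase (S1) and the last index the final post-contrast
phase (Slast).  Preprocessing brings every series to an isotropic grid
(cubic B-spline for images, nearest neighbour for label masks) and puts
intensities on a common scale by z-scoring against a reference region
(conventionally the pectoralis muscle) and rescaling by 100.

Kinetic voxel classification is deliberately performed on *raw*
intensities: the 50%/10% rules are ratios, and the shift introduced by
z-scoring would corrupt them.  Normalization is applied only to the
volume used for radiomic feature extraction, and one shared affine map
per patient must be used if several phases are normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import GeometryError, InvalidParameterError, NormalizationError

__all__ = [
    "DceSeries",
    "PreprocessConfig",
    "resample_isotropic",
    "normalize_zscore",
    "make_zscore_map",
]


@dataclass
class DceSeries:
    """Ordered stack of co-registered 3-D phases of one DCE acquisition.

    Parameters
    ----------
    phases
        List of 3-D arrays (signal intensity, arbitrary units), ordered
        pre-contrast first.  All phases must share shape.
    voxel_spacing
        Physical voxel size in mm per axis (array index order).
    """

    phases: list[np.ndarray]
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.phases) < 3:
            raise InvalidParameterError(
                "a DCE series needs >= 3 phases (pre, first post, last post)"
            )
        shapes = {p.shape for p in self.phases}
        if len(shapes) != 1:
            raise GeometryError(f"phases have inconsistent shapes: {shapes}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise InvalidParameterError("voxel spacing must be positive")
        self.phases = [np.asarray(p, dtype=np.float64) for p in self.phases]
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def pre(self) -> np.ndarray:
        """Pre-contrast volume S0."""
        return self.phases[0]

    @property
    def first_post(self) -> np.ndarray:
        """First post-contrast volume S1."""
        return self.phases[1]

    @property
    def last_post(self) -> np.ndarray:
        """Final post-contrast volume Slast."""
        return self.phases[-1]

    @property
    def n_post_phases(self) -> int:
        return len(self.phases) - 1

    @property
    def shape(self) -> tuple[int, ...]:
        return self.phases[0].shape


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    ``target_spacing`` is the isotropic output spacing in mm.  Images are
    interpolated with cubic B-splines, masks with nearest neighbour.
    Normalization is a per-patient z-score against a reference region,
    rescaled by ``scale`` (so the reference region ends up with mean 0
    and SD ``scale``); ``bin_width`` is the fixed discretization width
    applied downstream on that rescaled intensity axis.
    """

    target_spacing: float = 1.0
    scale: float = 100.0
    bin_width: float = 25.0

    def __post_init__(self) -> None:
        if self.target_spacing <= 0:
            raise InvalidParameterError("target_spacing must be > 0")
        if self.bin_width <= 0:
            raise InvalidParameterError("bin_width must be > 0")


def _to_sitk(volume: np.ndarray, spacing: tuple[float, ...]) -> sitk.Image:
    img = sitk.GetImageFromArray(np.asarray(volume))
    # SimpleITK spacing is (x, y, z) while numpy indexes (z, y, x)
    img.SetSpacing(tuple(reversed(spacing)))
    return img


def _resample_one(
    volume: np.ndarray,
    spacing: tuple[float, ...],
    target: float,
    interpolator: int,
) -> np.ndarray:
    img = _to_sitk(volume, spacing)
    old_size = np.array(img.GetSize(), dtype=float)
    old_spacing = np.array(img.GetSpacing(), dtype=float)
    new_size = np.round(old_size * old_spacing / target).astype(int)
    new_size = np.maximum(new_size, 1)
    res = sitk.Resample(
        img,
        [int(s) for s in new_size],
        sitk.Transform(),
        interpolator,
        img.GetOrigin(),
        (target,) * 3,
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
    )
    return sitk.GetArrayFromImage(res)


def resample_isotropic(
    series: DceSeries,
    mask: np.ndarray | None = None,
    config: PreprocessConfig | None = None,
) -> tuple[DceSeries, np.ndarray | None]:
    """Resample all phases (cubic B-spline) and a mask (nearest neighbour).

    The output grid has isotropic ``config.target_spacing`` voxels and
    preserves the physical extent of the input to within one voxel.
    If the series is already on the target grid it is returned unchanged.
    """
    config = config or PreprocessConfig()
    if mask is not None and mask.shape != series.shape:
        raise GeometryError(
            f"mask shape {mask.shape} does not match series shape {series.shape}"
        )
    t = config.target_spacing
    if all(abs(s - t) < 1e-9 for s in series.voxel_spacing):
        return series, mask
    phases = [
        _resample_one(p, series.voxel_spacing, t, sitk.sitkBSpline)
        for p in series.phases
    ]
    out_mask = None
    if mask is not None:
        out_mask = _resample_one(
            mask.astype(np.uint16), series.voxel_spacing, t, sitk.sitkNearestNeighbor
        )
    return DceSeries(phases, (t, t, t)), out_mask


def make_zscore_map(
    volume: np.ndarray,
    reference_mask: np.ndarray,
    config: PreprocessConfig | None = None,
):
    """Build the patient's shared affine normalization map.

    The map is ``x -> (x - mean_ref) / sd_ref * scale`` with the reference
    statistics taken from ``volume`` over ``reference_mask``.  Apply the
    same map to every phase that feeds feature extraction so kinetic
    ratios stay comparable across phases.
    """
    config = config or PreprocessConfig()
    ref = np.asarray(volume, dtype=np.float64)[np.asarray(reference_mask) > 0]
    if ref.size == 0:
        raise NormalizationError("reference region is empty")
    mean, sd = float(ref.mean()), float(ref.std())
    if sd <= 0 or not np.isfinite(sd):
        raise NormalizationError("reference region has zero intensity SD")

    def apply(x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - mean) / sd * config.scale

    apply.mean_ = mean  # type: ignore[attr-defined]
    apply.sd_ = sd  # type: ignore[attr-defined]
    return apply


def normalize_zscore(
    volume: np.ndarray,
    reference_mask: np.ndarray,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """Z-score ``volume`` against its own reference region, rescaled.

    Output intensities satisfy mean 0 / SD ``config.scale`` over the
    reference region.  The map is affine, so voxel rank order is
    preserved exactly.
    """
    return make_zscore_map(volume, reference_mask, config)(volume)
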