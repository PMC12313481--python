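"""Feature-extraction configuration and the closed-form inventory.

The extractor computes, per ROI, 14 shape descriptors on the original
geometry plus, for each of 13 image types (original, 4 Laplacian-of-
Gaussian scales, 8 single-level stationary-wavelet sub-bands):

* 18 first-order statistics,
* 22 or 24 gray-level co-occurrence (GLCM) features,
* 14 gray-level dependence (GLDM) features,
* 16 gray-level run-length (GLRLM) features,
* 16 gray-level size-zone (GLSZM) features.

Total = 14 + 13 * (18 + glcm + 14 + 16 + 16), i.e. 1132 features with
the 22-feature GLCM set (whole-tumor preset) and 1158 with the full
24-feature set (washout preset).  The 22-feature set drops SumAverage
(redundant with twice the joint average on a symmetric matrix) and MCC
(the costliest GLCM feature); the choice of which two to drop is a
configuration decision, the counts are the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import InvalidParameterError

__all__ = ["FeatureConfig", "feature_inventory", "GLCM_ALL", "GLCM_22"]

N_IMAGE_TYPES = 13  # original + 4 LoG + 8 wavelet sub-bands
N_SHAPE = 14
N_FIRSTORDER = 18
N_GLDM = 14
N_GLRLM = 16
N_GLSZM = 16

GLCM_ALL: tuple[str, ...] = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
)

#: 22-feature GLCM subset: drops SumAverage and MCC.
GLCM_22: tuple[str, ...] = tuple(
    n for n in GLCM_ALL if n not in ("SumAverage", "MCC")
)


@dataclass(frozen=True)
class FeatureConfig:
    """Pinned configuration of one extraction run.

    ``log_sigmas`` are Laplacian-of-Gaussian scales in mm (must yield 4
    images for the default bank), ``wavelet`` the PyWavelets name used
    for the 8 single-level 3-D sub-bands.  ``bin_width`` is the fixed
    discretization width on the (normalized) intensity axis, anchored at
    the ROI minimum.  ``glcm_features`` selects the 22- or 24-feature
    GLCM set.
    """

    log_sigmas: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    wavelet: str = "coif1"
    glcm_features: tuple[str, ...] = GLCM_22
    bin_width: float = 25.0
    min_roi_voxels: int = 10
    roi_tag: str = "whole_tumor"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise InvalidParameterError("bin_width must be > 0")
        if len(self.log_sigmas) != 4:
            raise InvalidParameterError("the image bank expects 4 LoG scales")
        unknown = set(self.glcm_features) - set(GLCM_ALL)
        if unknown:
            raise InvalidParameterError(f"unknown GLCM features: {sorted(unknown)}")

    @classmethod
    def whole_tumor(cls, **kw) -> "FeatureConfig":
        """Preset of the whole-tumor run: 22 GLCM features, 1132 total."""
        kw.setdefault("glcm_features", GLCM_22)
        kw.setdefault("roi_tag", "whole_tumor")
        return cls(**kw)

    @classmethod
    def washout(cls, **kw) -> "FeatureConfig":
        """Preset of the washout-region run: 24 GLCM features, 1158 total."""
        kw.setdefault("glcm_features", GLCM_ALL)
        kw.setdefault("roi_tag", "washout")
        return cls(**kw)


def feature_inventory(config: FeatureConfig) -> dict[str, int]:
    """Per-class feature counts implied by a configuration.

    Returns the closed-form counts
    ``total = 14 + 13 * (18 + n_glcm + 14 + 16 + 16)``.
    """
    n_glcm = len(config.glcm_features)
    counts = {
        "shape": N_SHAPE,
        "first_order": N_FIRSTORDER * N_IMAGE_TYPES,
        "glcm": n_glcm * N_IMAGE_TYPES,
        "gldm": N_GLDM * N_IMAGE_TYPES,
        "glrlm": N_GLRLM * N_IMAGE_TYPES,
        "glszm": N_GLSZM * N_IMAGE_TYPES,
    }
    counts["total"] = sum(counts.values())
    return counts
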