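"""Voxel-wise kinetic-curve classification into tumor subregions.

The enhancing part of the tumor is the set of voxels whose signal rises
by more than 50% from pre-contrast (S0) to first post-contrast (S1).
Each enhancing voxel is then classified by its late relative change
r = (Slast - S1) / S1:

* washout    (code 1): r < -10%  -- most suspicious pattern
* plateau    (code 2): |r| <= 10%
* persistent (code 3): r > +10%

Boundary conventions follow the clinical wording: the 50% gate and the
persistent/washout cutoffs are strict inequalities, the plateau band is
the closed interval.  All rules are ratios, so classification is
invariant under global intensity rescaling; it must be run on raw (not
z-scored) intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, SegmentationError
from .preprocess import DceSeries

__all__ = [
    "WASHOUT",
    "PLATEAU",
    "PERSISTENT",
    "KineticThresholds",
    "SubregionMap",
    "enhancement_mask",
    "classify_enhancement_voxels",
    "largest_component",
    "segment_tumor",
]

logger = logging.getLogger(__name__)

#: Subregion label codes, ordered by clinical suspiciousness (1 worst).
WASHOUT, PLATEAU, PERSISTENT = 1, 2, 3


@dataclass(frozen=True)
class KineticThresholds:
    """Thresholds of the two-stage voxel classification.

    ``enhancement_gate`` is the relative S0->S1 rise required for a voxel
    to count as enhancing (strict >).  ``late_delta`` is the half-width
    of the plateau band on the relative S1->Slast change: plateau is the
    closed interval [-late_delta, +late_delta], persistent strictly
    above, washout strictly below.
    """

    enhancement_gate: float = 0.50
    late_delta: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.late_delta < self.enhancement_gate:
            raise InvalidParameterError(
                "thresholds must satisfy 0 < late_delta < enhancement_gate"
            )


@dataclass
class SubregionMap:
    """Integer label volume partitioning the enhanced tumor.

    Codes: 0 non-enhancing/outside, 1 washout, 2 plateau, 3 persistent.
    The union of labels 1-3 equals the enhancement mask by construction.
    """

    labels: np.ndarray
    voxel_spacing: tuple[float, float, float]
    quality: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if not np.isin(np.unique(self.labels), [0, 1, 2, 3]).all():
            raise InvalidParameterError("subregion labels must be in {0,1,2,3}")

    @property
    def enhancement(self) -> np.ndarray:
        """Binary mask of all enhancing voxels (labels 1-3)."""
        return self.labels > 0

    def region(self, code: int) -> np.ndarray:
        return self.labels == code


def enhancement_mask(
    s0: np.ndarray,
    s1: np.ndarray,
    tumor_mask: np.ndarray,
    thresholds: KineticThresholds = KineticThresholds(),
) -> tuple[np.ndarray, dict]:
    """Gate tumor voxels on early enhancement.

    A voxel is kept iff it lies in the tumor mask, has S0 > 0 and finite
    intensities, and (S1-S0)/S0 strictly exceeds the gate.  Voxels with
    non-positive or non-finite baseline are excluded and counted in the
    returned quality report rather than classified.
    """
    s0 = np.asarray(s0, dtype=np.float64)
    s1 = np.asarray(s1, dtype=np.float64)
    tumor = np.asarray(tumor_mask) > 0
    if s0.shape != s1.shape or s0.shape != tumor.shape:
        raise SegmentationError("S0, S1 and tumor mask shapes differ")
    if not tumor.any():
        raise SegmentationError("tumor mask is empty")

    finite = np.isfinite(s0) & np.isfinite(s1)
    valid = tumor & finite & (s0 > 0)
    report = {
        "n_tumor_voxels": int(tumor.sum()),
        "n_nonpositive_baseline": int((tumor & finite & (s0 <= 0)).sum()),
        "n_nonfinite": int((tumor & ~finite).sum()),
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        rise = (s1 - s0) / s0
    mask = valid & (rise > thresholds.enhancement_gate)
    report["n_enhancing"] = int(mask.sum())
    return mask, report


def classify_enhancement_voxels(
    s1: np.ndarray,
    slast: np.ndarray,
    enh_mask: np.ndarray,
    thresholds: KineticThresholds = KineticThresholds(),
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    quality: dict | None = None,
) -> SubregionMap:
    """Classify enhancing voxels by late relative change into 1/2/3."""
    s1 = np.asarray(s1, dtype=np.float64)
    slast = np.asarray(slast, dtype=np.float64)
    enh = np.asarray(enh_mask) > 0
    if not enh.any():
        raise SegmentationError("enhancement mask is empty")
    # the 50% gate guarantees S1 > 1.5*S0 > 0 inside the mask
    assert (s1[enh] > 0).all(), "S1 must be positive inside the enhancement mask"

    with np.errstate(divide="ignore", invalid="ignore"):
        r = (slast - s1) / s1
    labels = np.zeros(s1.shape, dtype=np.uint8)
    labels[enh & (r < -thresholds.late_delta)] = WASHOUT
    labels[enh & (r > thresholds.late_delta)] = PERSISTENT
    labels[enh & (labels == 0)] = PLATEAU
    return SubregionMap(labels, voxel_spacing, quality or {})


def largest_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Keep only the largest connected component of a binary mask.

    Ties on voxel count are broken toward the component with the
    lexicographically smallest centroid (and a warning is logged).
    ``connectivity`` is 26 (default, full 3x3x3 neighbourhood) or 6.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise SegmentationError("cannot take largest component of an empty mask")
    if connectivity not in (6, 26):
        raise InvalidParameterError("connectivity must be 6 or 26")
    structure = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    lab, n = ndimage.label(mask, structure=structure)
    if n == 1:
        return mask
    counts = np.bincount(lab.ravel())[1:]
    best = int(np.max(counts))
    cand = np.flatnonzero(counts == best) + 1
    if len(cand) > 1:
        centroids = ndimage.center_of_mass(mask, lab, cand)
        cand = [c for _, c in sorted(zip(map(tuple, centroids), cand))]
        logger.warning(
            "largest_component: %d equal-size components; keeping the one "
            "with smallest centroid",
            len(cand),
        )
    return lab == cand[0]


def segment_tumor(
    series: DceSeries,
    tumor_mask: np.ndarray,
    thresholds: KineticThresholds = KineticThresholds(),
    keep_largest: bool = True,
    connectivity: int = 26,
) -> SubregionMap:
    """Full subregion segmentation from a DCE series and a tumor mask.

    Optionally restricts the tumor mask to its largest connected cluster
    (multi-lesion rule) before gating and classifying.
    """
    tumor = np.asarray(tumor_mask) > 0
    if keep_largest and tumor.any():
        tumor = largest_component(tumor, connectivity=connectivity)
    enh, report = enhancement_mask(series.pre, series.first_post, tumor, thresholds)
    if not enh.any():
        return SubregionMap(
            np.zeros(series.shape, dtype=np.uint8), series.voxel_spacing, report
        )
    return classify_enhancement_voxels(
        series.first_post,
        series.last_post,
        enh,
        thresholds,
        series.voxel_spacing,
        report,
    )
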