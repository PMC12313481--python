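"""Per-tumor kinetic-heterogeneity statistics.

From a :class:`~kinhet.segmentation.SubregionMap` and the DCE phases this
module computes the tumor-level kinetic summary: the voxel proportions of
the washout/plateau/persistent components, the kinetic-heterogeneity
entropy

    KH = -sum_i P_i * log_k(P_i),    k = 3,  0*log(0) := 0,

which ranges from 0 (a single component) to 1 (equal thirds), the peak
relative enhancement over the enhanced region, the enhanced volume in
mm^3, and the predominant and worst (most suspicious) curve types under
the suspiciousness ordering washout(1) > plateau(2) > persistent(3).

Proportions are always reported in code order (washout, plateau,
persistent).  Tumors with no enhancing voxel have an undefined profile
and raise :class:`~kinhet.errors.UndefinedProfileError` rather than
producing zero-filled rows.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import InvalidParameterError, UndefinedProfileError
from .segmentation import PERSISTENT, PLATEAU, SubregionMap, WASHOUT

__all__ = [
    "KineticProfile",
    "component_proportions",
    "kinetic_heterogeneity",
    "peak_enhancement",
    "enhanced_volume",
    "predominant_type",
    "worst_type",
    "kinetic_profile",
]

_SUSPICIOUSNESS = (WASHOUT, PLATEAU, PERSISTENT)  # 1 worst, 3 most benign


@dataclass
class KineticProfile:
    """Tumor-level kinetic parameters (one row per patient)."""

    washout_pct: float
    plateau_pct: float
    persistent_pct: float
    kinetic_heterogeneity: float
    peak_enhancement: float
    enhanced_volume: float  # mm^3
    predominant_type: int  # 1 washout / 2 plateau / 3 persistent
    worst_type: int

    def to_dict(self) -> dict:
        return asdict(self)


def component_proportions(subregions: SubregionMap) -> np.ndarray:
    """Proportions (P_washout, P_plateau, P_persistent) of enhanced voxels."""
    labels = subregions.labels
    counts = np.array([(labels == c).sum() for c in _SUSPICIOUSNESS], dtype=float)
    total = counts.sum()
    if total == 0:
        raise UndefinedProfileError("no enhancing voxels: kinetic profile undefined")
    return counts / total


def kinetic_heterogeneity(proportions, k: int = 3) -> float:
    """Normalized Shannon entropy of the component proportions.

    ``KH = -sum P_i log_k P_i`` with the convention ``0 log 0 = 0``.
    The number of categories ``k`` is fixed at 3 regardless of how many
    components are actually present, so a single-component tumor scores
    exactly 0 and the uniform mixture scores exactly 1.
    """
    p = np.asarray(proportions, dtype=np.float64)
    if p.ndim != 1 or (p < 0).any():
        raise InvalidParameterError("proportions must be a nonnegative vector")
    if abs(p.sum() - 1.0) > 1e-6:
        raise InvalidParameterError(f"proportions must sum to 1, got {p.sum():.8f}")
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(k))).sum() + 0.0)


def peak_enhancement(s0: np.ndarray, s1: np.ndarray, enh_mask: np.ndarray) -> float:
    """Maximum relative S0->S1 enhancement over the enhanced region."""
    enh = np.asarray(enh_mask) > 0
    if not enh.any():
        raise UndefinedProfileError("empty enhancement mask: peak undefined")
    s0 = np.asarray(s0, dtype=np.float64)[enh]
    s1 = np.asarray(s1, dtype=np.float64)[enh]
    return float(((s1 - s0) / s0).max())


def enhanced_volume(enh_mask: np.ndarray, voxel_spacing) -> float:
    """Physical volume (mm^3) of the enhancing region."""
    spacing = np.asarray(voxel_spacing, dtype=float)
    if (spacing <= 0).any():
        raise InvalidParameterError("voxel spacing must be positive")
    return float((np.asarray(enh_mask) > 0).sum() * spacing.prod())


def predominant_type(proportions) -> int:
    """Code of the largest component; ties go to the more suspicious type."""
    p = np.asarray(proportions, dtype=np.float64)
    # argmax returns the first maximum; order is already by suspiciousness
    return _SUSPICIOUSNESS[int(np.argmax(p))]


def worst_type(proportions) -> int:
    """Most suspicious component present (washout > plateau > persistent)."""
    p = np.asarray(proportions, dtype=np.float64)
    for code, pi in zip(_SUSPICIOUSNESS, p):
        if pi > 0:
            return code
    raise InvalidParameterError("all proportions are zero")


def kinetic_profile(
    subregions: SubregionMap, s0: np.ndarray, s1: np.ndarray
) -> KineticProfile:
    """Assemble the full per-tumor kinetic parameter row."""
    p = component_proportions(subregions)
    enh = subregions.enhancement
    return KineticProfile(
        washout_pct=float(p[0]),
        plateau_pct=float(p[1]),
        persistent_pct=float(p[2]),
        kinetic_heterogeneity=kinetic_heterogeneity(p),
        peak_enhancement=peak_enhancement(s0, s1, enh),
        enhanced_volume=enhanced_volume(enh, subregions.voxel_spacing),
        predominant_type=predominant_type(p),
        worst_type=worst_type(p),
    )
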