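"""First-order (intensity histogram) statistics of a masked volume.

Eighteen features.  Moments, percentiles and energies are computed on
the raw masked intensities; Entropy and Uniformity use the fixed-bin-
width discretized histogram (bins anchored at the ROI minimum), matching
the discretization the texture matrices use.
"""

from __future__ import annotations

import numpy as np

from ..errors import DegenerateRoiError

__all__ = ["firstorder_features", "FIRSTORDER_FEATURES", "discretize"]

FIRSTORDER_FEATURES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray levels, anchored at the ROI minimum.

    Level of voxel v is ``floor((v - min) / width) + 1`` (so levels start
    at 1); adding any constant to the whole ROI leaves the levels
    unchanged, which keeps texture features shift-invariant.
    """
    values = np.asarray(values, dtype=np.float64)
    levels = np.floor((values - values.min()) / bin_width).astype(np.int64) + 1
    return levels


def firstorder_features(
    values: np.ndarray,
    bin_width: float,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """Compute the 18 first-order statistics of the masked intensities."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise DegenerateRoiError("no voxels in ROI")

    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    if var > 0:
        m = x - mean
        skew = (m**3).mean() / var**1.5
        kurt = (m**4).mean() / var**2  # Pearson (non-excess) kurtosis
    else:
        skew, kurt = 0.0, 0.0

    levels = discretize(x, bin_width)
    p = np.bincount(levels)[1:].astype(np.float64)
    p = p[p > 0] / x.size

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume * energy),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float((p**2).sum()),
    }
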