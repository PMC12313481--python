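"""ROI feature-vector extraction over the 13-image bank."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from ..errors import DegenerateRoiError, GeometryError
from ..preprocess import DceSeries
from .config import FeatureConfig, feature_inventory
from .firstorder import FIRSTORDER_FEATURES, discretize, firstorder_features
from .imagebank import build_image_bank
from .shape import shape_features
from .texture import (
    gldm_features,
    glrlm_features,
    glszm_features,
    glcm_features,
)

__all__ = ["extract_feature_vector", "extract_feature_table", "config_hash"]


def config_hash(config: FeatureConfig) -> str:
    """Short provenance hash of a feature configuration."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def extract_feature_vector(
    series: DceSeries | np.ndarray,
    roi_mask: np.ndarray,
    config: FeatureConfig = FeatureConfig(),
    voxel_spacing=None,
) -> pd.Series:
    """Extract the full named feature vector of one ROI.

    The intensity source is the first post-contrast phase when a
    :class:`DceSeries` is given, or the supplied 3-D volume directly.
    Shape features are computed once on the mask geometry; first-order
    and texture features are computed per image type on fixed-bin-width
    discretized intensities anchored at the ROI minimum.  Vector length
    equals ``feature_inventory(config)["total"]``.
    """
    if isinstance(series, DceSeries):
        volume = series.first_post
        spacing = series.voxel_spacing
    else:
        volume = np.asarray(series, dtype=np.float64)
        spacing = tuple(voxel_spacing) if voxel_spacing is not None else (1.0, 1.0, 1.0)
    mask = np.asarray(roi_mask) > 0
    if mask.shape != volume.shape:
        raise GeometryError("ROI mask shape does not match the volume")
    n_roi = int(mask.sum())
    if n_roi < config.min_roi_voxels:
        raise DegenerateRoiError(
            f"ROI has {n_roi} voxels, below the minimum of {config.min_roi_voxels}"
        )

    voxel_volume = float(np.prod(spacing))
    out: dict[str, float] = {}
    for name, value in shape_features(mask, spacing).items():
        out[f"original_shape_{name}"] = value

    bank = build_image_bank(volume, spacing, config)
    for img_name, img in bank.items():
        vals = img[mask]
        levels_flat = discretize(vals, config.bin_width)
        level_vol = np.zeros(img.shape, dtype=np.int64)
        level_vol[mask] = levels_flat

        fo = firstorder_features(vals, config.bin_width, voxel_volume)
        for fname in FIRSTORDER_FEATURES:
            out[f"{img_name}_firstorder_{fname}"] = fo[fname]
        for fname, v in glcm_features(level_vol, mask, config.glcm_features).items():
            out[f"{img_name}_glcm_{fname}"] = v
        for fname, v in gldm_features(level_vol, mask).items():
            out[f"{img_name}_gldm_{fname}"] = v
        for fname, v in glrlm_features(level_vol, mask).items():
            out[f"{img_name}_glrlm_{fname}"] = v
        for fname, v in glszm_features(level_vol, mask).items():
            out[f"{img_name}_glszm_{fname}"] = v

    vec = pd.Series(out, name=config.roi_tag)
    expected = feature_inventory(config)["total"]
    assert len(vec) == expected, f"extracted {len(vec)} features, expected {expected}"
    if not np.isfinite(vec.to_numpy()).all():
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise DegenerateRoiError(f"non-finite features on valid ROI: {bad[:5]}")
    return vec


def extract_feature_table(
    cases: dict[str, tuple[DceSeries | np.ndarray, np.ndarray]],
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Stack per-patient feature vectors into a patients x features table.

    ``cases`` maps patient id to ``(series_or_volume, roi_mask)``.
    The table carries the ROI tag and config hash in ``attrs``.
    """
    rows = {
        pid: extract_feature_vector(vol, mask, config)
        for pid, (vol, mask) in cases.items()
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.attrs["roi_tag"] = config.roi_tag
    table.attrs["config_hash"] = config_hash(config)
    return table
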