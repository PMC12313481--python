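"""Derived-image bank: original, LoG scales, wavelet sub-bands.

Thirteen image types feed the texture/first-order features: the original
volume, four Laplacian-of-Gaussian responses (scales in mm), and the
eight sub-bands of a single-level 3-D stationary (undecimated) wavelet
transform, named by the per-axis low/high-pass combination (LLL ... HHH).
The stationary transform keeps every sub-band on the original voxel
grid, so one ROI mask serves all image types.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from ..errors import InvalidParameterError
from .config import FeatureConfig

__all__ = ["build_image_bank", "WAVELET_BANDS"]

WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def _check_isotropic(spacing) -> float:
    s = np.asarray(spacing, dtype=float)
    if not np.allclose(s, s[0], rtol=1e-3):
        raise InvalidParameterError(
            f"image bank requires isotropically resampled input, got spacing {tuple(s)}"
        )
    return float(s[0])


def _swt_bands(volume: np.ndarray, wavelet: str) -> dict[str, np.ndarray]:
    """Single-level stationary wavelet sub-bands, same shape as input."""
    shape = volume.shape
    pad = [(0, (-n) % 2) for n in shape]  # swt needs even extents
    padded = np.pad(volume, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out = {}
    for key, band in coeffs.items():
        # pywt keys use 'a' (approximation) / 'd' (detail) per axis
        name = key.replace("a", "L").replace("d", "H")
        out[name] = band[tuple(slice(0, n) for n in shape)]
    return out


def build_image_bank(
    volume: np.ndarray,
    voxel_spacing=(1.0, 1.0, 1.0),
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, np.ndarray]:
    """Compute the 13 derived volumes of one input volume.

    Keys: ``original``, ``log-sigma-<s>mm`` for each configured scale,
    and ``wavelet-<band>`` for the 8 sub-bands.  Deterministic: same
    input and config give an identical bank.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise InvalidParameterError("image bank expects a 3-D volume")
    iso = _check_isotropic(voxel_spacing)

    bank: dict[str, np.ndarray] = {"original": volume}
    for sigma_mm in config.log_sigmas:
        sigma_vox = sigma_mm / iso
        # scale-normalized LoG response (multiplied by sigma^2)
        bank[f"log-sigma-{sigma_mm:g}mm"] = sigma_vox**2 * ndimage.gaussian_laplace(
            volume, sigma=sigma_vox
        )
    sub = _swt_bands(volume, config.wavelet)
    for band in WAVELET_BANDS:
        bank[f"wavelet-{band}"] = sub[band]
    return bank
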