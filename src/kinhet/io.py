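"""NIfTI / CSV / YAML round-tripping for the pipeline stages."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .preprocess import DceSeries
from .segmentation import SubregionMap

__all__ = [
    "save_volume",
    "load_volume",
    "save_series",
    "load_series",
    "save_subregions",
    "load_subregions",
    "load_yaml",
    "save_yaml",
]


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_volume(volume: np.ndarray, spacing, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(volume), _affine(spacing)), str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_series(series: DceSeries, out_dir: str | Path, stem: str = "phase") -> list[Path]:
    """Write one NIfTI per phase with a zero-padded phase index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return [
        save_volume(p, series.voxel_spacing, out / f"{stem}_{i:02d}.nii.gz")
        for i, p in enumerate(series.phases)
    ]


def load_series(paths: list[str | Path]) -> DceSeries:
    vols, spacing = [], None
    for p in paths:
        v, s = load_volume(p)
        vols.append(np.asarray(v, dtype=np.float64))
        spacing = spacing or s
    return DceSeries(vols, spacing)


def save_subregions(subregions: SubregionMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(
        subregions.labels.astype(np.uint8), _affine(subregions.voxel_spacing)
    )
    nib.save(img, str(path))
    return path


def load_subregions(path: str | Path) -> SubregionMap:
    labels, spacing = load_volume(path)
    return SubregionMap(np.asarray(labels, dtype=np.uint8), spacing)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path
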