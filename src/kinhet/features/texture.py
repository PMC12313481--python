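"""Gray-level texture matrices and their features on 3-D ROIs.

All four families operate on the fixed-bin-width discretized volume
(levels 1..Ng inside the ROI, 0 outside) with full 3-D aggregation:

* GLCM  — co-occurrence over the 13 unique 26-neighbourhood directions
  at distance 1; the symmetric matrix is built per direction, features
  are computed per direction and averaged.
* GLRLM — run lengths along the same 13 directions, features averaged.
* GLSZM — 26-connected iso-intensity zone sizes (single matrix).
* GLDM  — dependence counts over the 26-neighbourhood with gray-level
  tolerance alpha = 0 (single matrix).

Feature definitions follow the IBSI conventions; logarithms are base 2.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import GLCM_ALL

__all__ = [
    "glcm_features",
    "gldm_features",
    "glrlm_features",
    "glszm_features",
    "GLDM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
]

GLDM_FEATURES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

GLRLM_FEATURES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

_EPS = np.finfo(np.float64).tiny


def _directions13() -> list[tuple[int, int, int]]:
    """The 13 unique direction vectors of the 26-neighbourhood."""
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                d = (dz, dy, dx)
                if d == (0, 0, 0):
                    continue
                if d > (0, 0, 0):  # keep one of each +/- pair
                    dirs.append(d)
    return dirs


def _offsets26() -> list[tuple[int, int, int]]:
    dirs = _directions13()
    return dirs + [tuple(-c for c in d) for d in dirs]


def _pair_slices(shape, d):
    """Slices (src, dst) so that arr[dst] sits at offset d from arr[src]."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 1:
            src.append(slice(0, n - 1))
            dst.append(slice(1, n))
        elif step == -1:
            src.append(slice(1, n))
            dst.append(slice(0, n - 1))
        else:
            src.append(slice(0, n))
            dst.append(slice(0, n))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------- GLCM


def _glcm_one(p: np.ndarray, names) -> dict[str, float]:
    """Features of one normalized symmetric co-occurrence matrix."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    I, J = i[:, None], i[None, :]
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    ksum = np.bincount((I + J).astype(int).ravel(), weights=p.ravel())
    kdiff = np.bincount(np.abs(I - J).astype(int).ravel(), weights=p.ravel())
    s_idx = np.arange(len(ksum), dtype=np.float64)
    d_idx = np.arange(len(kdiff), dtype=np.float64)

    pz = p[p > 0]
    hxy = float(-(pz * np.log2(pz)).sum())
    pxz = px[px > 0]
    hx = float(-(pxz * np.log2(pxz)).sum())
    pxpy = px[:, None] * px[None, :]
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    pq = pxpy[pxpy > 0]
    hxy2 = float(-(pq * np.log2(pq)).sum())

    da = float((d_idx * kdiff).sum())
    off = I != J

    out: dict[str, float] = {}
    feats = {
        "Autocorrelation": lambda: float((I * J * p).sum()),
        "JointAverage": lambda: mu,
        "ClusterProminence": lambda: float(((I + J - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": lambda: float(((I + J - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": lambda: float(((I + J - 2 * mu) ** 2 * p).sum()),
        "Contrast": lambda: float(((I - J) ** 2 * p).sum()),
        "Correlation": lambda: (
            float(((I - mu) * (J - mu) * p).sum() / sigma2) if sigma2 > 0 else 1.0
        ),
        "DifferenceAverage": lambda: da,
        "DifferenceEntropy": lambda: float(
            -(kdiff[kdiff > 0] * np.log2(kdiff[kdiff > 0])).sum()
        ),
        "DifferenceVariance": lambda: float(((d_idx - da) ** 2 * kdiff).sum()),
        "Id": lambda: float((p / (1 + np.abs(I - J))).sum()),
        "Idm": lambda: float((p / (1 + (I - J) ** 2)).sum()),
        "Idmn": lambda: float((p / (1 + ((I - J) / ng) ** 2)).sum()),
        "Idn": lambda: float((p / (1 + np.abs(I - J) / ng)).sum()),
        "Imc1": lambda: (
            float((hxy - hxy1) / max(hx, _EPS)) if hx > 0 else 0.0
        ),
        "Imc2": lambda: float(np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))),
        "InverseVariance": lambda: float(
            (p[off] / (I - J)[off] ** 2).sum()
        ),
        "JointEnergy": lambda: float((p**2).sum()),
        "JointEntropy": lambda: hxy,
        "MaximumProbability": lambda: float(p.max()),
        "SumAverage": lambda: float((s_idx * ksum).sum()),
        "SumEntropy": lambda: float(
            -(ksum[ksum > 0] * np.log2(ksum[ksum > 0])).sum()
        ),
        "SumSquares": lambda: sigma2,
        "MCC": lambda: _mcc(p, px),
    }
    for name in names:
        out[name] = feats[name]()
    return out


def _mcc(p: np.ndarray, px: np.ndarray) -> float:
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    q = p[np.ix_(keep, keep)]
    m = q / px[keep][:, None]  # p(i,k)/px(i)
    w = q / px[keep][None, :]  # p(j,k)/px(k)
    eig = np.linalg.eigvals(m @ w.T)
    eig = np.sort(np.real(eig))[::-1]
    return float(np.sqrt(max(0.0, eig[1] if len(eig) > 1 else 0.0)))


def glcm_features(levels: np.ndarray, mask: np.ndarray, names=GLCM_ALL) -> dict:
    """Direction-averaged co-occurrence features (distance 1, symmetric)."""
    mask = np.asarray(mask) > 0
    g = np.where(mask, levels, 0).astype(np.int64)
    ng = int(g.max())
    acc: dict[str, float] = {n: 0.0 for n in names}
    used = 0
    for d in _directions13():
        src, dst = _pair_slices(g.shape, d)
        a, b = g[src], g[dst]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        pmat = np.zeros((ng, ng), dtype=np.float64)
        np.add.at(pmat, (a[valid] - 1, b[valid] - 1), 1.0)
        pmat = pmat + pmat.T  # symmetric co-occurrence
        pmat /= pmat.sum()
        for k, v in _glcm_one(pmat, names).items():
            acc[k] += v
        used += 1
    if used == 0:  # isolated voxels only
        return {n: 0.0 for n in names}
    return {k: v / used for k, v in acc.items()}


# ------------------------------------------------- shared P(i, s) family


def _matrix_stats(pmat: np.ndarray, nz: float, np_vox: int) -> dict[str, float]:
    """Generic features of a gray-level x size/length/dependence matrix.

    ``pmat`` is the unnormalized matrix (rows gray levels 1.., columns
    sizes 1..), ``nz`` the number of runs/zones/voxels it counts and
    ``np_vox`` the ROI voxel count.
    """
    p = pmat / nz
    ng, ns = p.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, ns + 1, dtype=np.float64)[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float((i.ravel() * pg).sum())
    mu_j = float((j.ravel() * ps).sum())
    pz = p[p > 0]
    return {
        "small": float((p / j**2).sum()),
        "large": float((p * j**2).sum()),
        "gln": float(nz * (pg**2).sum()),
        "glnn": float((pg**2).sum()),
        "sn": float(nz * (ps**2).sum()),
        "snn": float((ps**2).sum()),
        "pct": float(nz / np_vox),
        "glv": float((p * (i - mu_i) ** 2).sum()),
        "sv": float((p * (j - mu_j) ** 2).sum()),
        "entropy": float(-(pz * np.log2(pz)).sum()),
        "lgl": float((p / i**2).sum()),
        "hgl": float((p * i**2).sum()),
        "small_lgl": float((p / (i**2 * j**2)).sum()),
        "small_hgl": float((p * i**2 / j**2).sum()),
        "large_lgl": float((p * j**2 / i**2).sum()),
        "large_hgl": float((p * i**2 * j**2).sum()),
    }


_RLM_KEYS = (
    "small", "large", "gln", "glnn", "sn", "snn", "pct", "glv", "sv",
    "entropy", "lgl", "hgl", "small_lgl", "small_hgl", "large_lgl", "large_hgl",
)


# --------------------------------------------------------------- GLRLM


def _runs_one_direction(g: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """Gray level and length of every maximal run along direction d."""
    shape = g.shape
    same_next = np.zeros(shape, dtype=bool)
    src, dst = _pair_slices(shape, d)
    same_next[src] = (g[src] > 0) & (g[src] == g[dst])
    same_prev = np.zeros(shape, dtype=bool)
    src_b, dst_b = _pair_slices(shape, tuple(-c for c in d))
    same_prev[src_b] = (g[src_b] > 0) & (g[src_b] == g[dst_b])

    starts = (g > 0) & ~same_prev
    coords = np.argwhere(starts)
    n = len(coords)
    lengths = np.ones(n, dtype=np.int64)
    cur = coords.copy()
    active = same_next[tuple(coords.T)]
    step = np.asarray(d)
    while active.any():
        idx = np.flatnonzero(active)
        cur[idx] += step
        lengths[idx] += 1
        nxt = same_next[tuple(cur[idx].T)]
        active[:] = False
        active[idx[nxt]] = True
    return g[tuple(coords.T)], lengths


def glrlm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Direction-averaged run-length features over 13 directions."""
    mask = np.asarray(mask) > 0
    g = np.where(mask, levels, 0).astype(np.int64)
    ng = int(g.max())
    np_vox = int(mask.sum())
    acc = dict.fromkeys(GLRLM_FEATURES, 0.0)
    dirs = _directions13()
    for d in dirs:
        grays, lens = _runs_one_direction(g, d)
        pmat = np.zeros((ng, int(lens.max())), dtype=np.float64)
        np.add.at(pmat, (grays - 1, lens - 1), 1.0)
        s = _matrix_stats(pmat, float(len(grays)), np_vox)
        for name, key in zip(GLRLM_FEATURES, _RLM_KEYS):
            acc[name] += s[key]
    return {k: v / len(dirs) for k, v in acc.items()}


# --------------------------------------------------------------- GLSZM


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Size-zone features from 26-connected iso-intensity zones."""
    mask = np.asarray(mask) > 0
    g = np.where(mask, levels, 0).astype(np.int64)
    ng = int(g.max())
    structure = ndimage.generate_binary_structure(3, 3)
    grays, sizes = [], []
    for level in np.unique(g[g > 0]):
        lab, nzone = ndimage.label(g == level, structure=structure)
        if nzone:
            counts = np.bincount(lab.ravel())[1:]
            grays.extend([level] * nzone)
            sizes.extend(counts.tolist())
    grays = np.asarray(grays, dtype=np.int64)
    sizes = np.asarray(sizes, dtype=np.int64)
    pmat = np.zeros((ng, int(sizes.max())), dtype=np.float64)
    np.add.at(pmat, (grays - 1, sizes - 1), 1.0)
    s = _matrix_stats(pmat, float(len(grays)), int(mask.sum()))
    return {name: s[key] for name, key in zip(GLSZM_FEATURES, _RLM_KEYS)}


# ---------------------------------------------------------------- GLDM


def gldm_features(
    levels: np.ndarray, mask: np.ndarray, alpha: int = 0
) -> dict[str, float]:
    """Dependence-matrix features (26-neighbourhood, tolerance alpha)."""
    mask = np.asarray(mask) > 0
    g = np.where(mask, levels, 0).astype(np.int64)
    ng = int(g.max())
    dep = np.zeros(g.shape, dtype=np.int64)
    for d in _offsets26():
        src, dst = _pair_slices(g.shape, d)
        ok = (g[src] > 0) & (g[dst] > 0) & (np.abs(g[src] - g[dst]) <= alpha)
        contrib = np.zeros(g.shape, dtype=np.int64)
        contrib[src] = ok
        dep += contrib
    sizes = dep[mask] + 1  # dependence size includes the center voxel
    grays = g[mask]
    pmat = np.zeros((ng, int(sizes.max())), dtype=np.float64)
    np.add.at(pmat, (grays - 1, sizes - 1), 1.0)
    s = _matrix_stats(pmat, float(mask.sum()), int(mask.sum()))
    gldm_keys = (
        "small", "large", "gln", "sn", "snn", "glv", "sv", "entropy",
        "lgl", "hgl", "small_lgl", "small_hgl", "large_lgl", "large_hgl",
    )
    return {name: s[key] for name, key in zip(GLDM_FEATURES, gldm_keys)}
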