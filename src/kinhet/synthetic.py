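"""Synthetic DCE phantoms and feature cohorts with known ground truth.

Patient DCE-MRI data for this kind of study are not publicly deposited,
so every downstream stage is exercised on synthetic inputs with exact
ground truth instead.  Two generators are provided:

* :func:`simulate_phantom` builds a 4-D DCE series (1 pre-contrast +
  ``n_post_phases`` post-contrast volumes) around an ellipsoidal,
  optionally lobulated, tumor whose voxels follow one of the three
  kinetic archetypes (persistent / washout / plateau) sampled from
  configurable class proportions; the realized voxel-wise labels are
  returned as ground truth.
* :func:`simulate_feature_cohort` draws a patients-by-features table
  with a configurable number of informative columns separated between
  the two outcome classes by a given standardized mean difference; it
  exercises the model stage (screening, LASSO, ROC, DCA) with known
  signal.

Voxel time-intensity curves are piecewise linear in phase index: the
voxel rises from its baseline S0 by ``uptake_fraction`` at the first
post-contrast phase and then moves linearly to the last phase, whose
value is the first-post value times ``1 + late_slope_fraction``.  Only
the pre, first-post and last-post phases enter the kinetic rules, so the
intermediate shape is immaterial; linearity is the simplest choice.
Noise is additive i.i.d. Gaussian per voxel-phase (the low-SNR Rician
regime is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import sph_harm_y

from .errors import InvalidParameterError
from .preprocess import DceSeries
from .segmentation import PERSISTENT, PLATEAU, SubregionMap, WASHOUT

__all__ = [
    "CurveArchetype",
    "PhantomSpec",
    "CohortSpec",
    "ARCHETYPES",
    "BACKGROUND",
    "simulate_voxel_curve",
    "simulate_phantom",
    "PhantomResult",
    "simulate_feature_cohort",
    "FeatureCohort",
]


@dataclass(frozen=True)
class CurveArchetype:
    """Parameters of one kinetic curve type.

    ``uptake_fraction`` is the relative rise from pre-contrast to the
    first post-contrast phase (> 0.5 for enhancing archetypes);
    ``late_slope_fraction`` is the relative change from first to last
    post-contrast phase (> +0.10 persistent, < -0.10 washout, within
    +/-0.10 plateau).
    """

    name: str
    baseline: float = 100.0
    uptake_fraction: float = 0.8
    late_slope_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise InvalidParameterError("baseline must be positive")


#: Default enhancing archetypes, one per kinetic class.  Uptake fractions
#: are well above the 50% gate and late slopes well outside the +/-10%
#: plateau band so that, noiselessly, each archetype classifies into its
#: own class with margin.
ARCHETYPES: dict[int, CurveArchetype] = {
    WASHOUT: CurveArchetype("washout", 100.0, 1.0, -0.30),
    PLATEAU: CurveArchetype("plateau", 100.0, 0.9, 0.0),
    PERSISTENT: CurveArchetype("persistent", 100.0, 0.8, 0.30),
}

#: Non-enhancing background tissue (uptake below the 50% gate).
BACKGROUND = CurveArchetype("background", 100.0, 0.15, 0.0)


@dataclass
class PhantomSpec:
    """Specification of one synthetic DCE phantom.

    ``class_proportions`` are (p_washout, p_plateau, p_persistent) and
    must sum to 1.  ``tumor_semi_axes`` are ellipsoid semi-axes in mm;
    ``lobulation`` perturbs the ellipsoid radius by a degree-3 spherical
    harmonic with the given relative amplitude (masks stay connected by
    construction).  ``noise_sd`` is the additive Gaussian noise SD in
    signal units (archetype baselines default to 100).
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_semi_axes: tuple[float, float, float] = (16.0, 14.0, 12.0)
    lobulation: float = 0.0
    class_proportions: tuple[float, float, float] = (0.25, 0.34, 0.41)
    noise_sd: float = 0.0
    n_post_phases: int = 8
    seed: int = 0
    archetypes: dict[int, CurveArchetype] = field(
        default_factory=lambda: dict(ARCHETYPES)
    )
    background: CurveArchetype = BACKGROUND

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(
                "class_proportions must be nonnegative and sum to 1"
            )
        if self.n_post_phases < 2:
            raise InvalidParameterError("n_post_phases must be >= 2")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass
class CohortSpec:
    """Specification of a synthetic two-arm feature cohort.

    ``feature_effect`` is the standardized mean difference applied to the
    first ``n_informative`` feature columns between outcome classes;
    remaining columns are pure noise.
    """

    n_patients: int = 200
    prevalence: float = 0.5
    feature_effect: float = 1.5
    n_features: int = 100
    n_informative: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise InvalidParameterError("prevalence must be in (0, 1)")
        if self.n_informative > self.n_features:
            raise InvalidParameterError("n_informative must be <= n_features")
        if self.n_patients < 4:
            raise InvalidParameterError("cohort needs at least 4 patients")


def simulate_voxel_curve(
    archetype: CurveArchetype,
    n_post_phases: int = 8,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Time-intensity curve of one voxel (length ``1 + n_post_phases``).

    Element 0 is the pre-contrast value (the baseline), element 1 is
    ``baseline * (1 + uptake_fraction)``, the last element is the
    first-post value times ``1 + late_slope_fraction``, with intermediate
    post phases linear in phase index.  Gaussian noise of SD ``noise_sd``
    is added to every sample.
    """
    if n_post_phases < 2:
        raise InvalidParameterError("n_post_phases must be >= 2")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    s1 = archetype.baseline * (1.0 + archetype.uptake_fraction)
    slast = s1 * (1.0 + archetype.late_slope_fraction)
    post = np.linspace(s1, slast, n_post_phases)
    curve = np.concatenate([[archetype.baseline], post])
    if noise_sd > 0:
        curve = curve + rng.normal(0.0, noise_sd, size=curve.shape)
    return curve


def _tumor_mask(spec: PhantomSpec) -> np.ndarray:
    """Ellipsoid (optionally lobulated) mask centered in the grid."""
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    semi = np.asarray(spec.tumor_semi_axes, dtype=float)
    extent_mm = (shape - 1) * spacing / 2.0
    if ((semi * (1.0 + abs(spec.lobulation))) > extent_mm).any():
        raise InvalidParameterError("tumor geometry exceeds the phantom grid")
    center = (shape - 1) / 2.0
    axes = [
        (np.arange(n) - c) * s for n, c, s in zip(shape, center, spacing)
    ]
    z, y, x = np.meshgrid(*axes, indexing="ij")
    u, v, w = z / semi[0], y / semi[1], x / semi[2]
    rho = np.sqrt(u * u + v * v + w * w)
    if spec.lobulation == 0:
        return rho <= 1.0
    r = np.maximum(rho, 1e-12)
    theta = np.arccos(np.clip(u / r, -1.0, 1.0))
    phi = np.arctan2(w, v)
    # degree-3 real spherical harmonic: smooth, low-order lobulation,
    # normalized to unit peak amplitude over the grid
    pert = np.real(sph_harm_y(3, 2, theta, phi))
    pert = pert / max(np.abs(pert).max(), 1e-12)
    return rho <= 1.0 + spec.lobulation * pert


@dataclass
class PhantomResult:
    """A simulated phantom: series, tumor mask, and voxel ground truth."""

    series: DceSeries
    tumor_mask: np.ndarray
    truth: SubregionMap
    class_counts: dict[int, int]


def simulate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Simulate one DCE phantom with voxel-level ground-truth labels.

    Every in-mask voxel is assigned a kinetic class by sampling
    ``class_proportions``; out-of-mask voxels follow the non-enhancing
    background archetype and carry ground-truth label 0.  The realized
    per-class voxel counts are returned (they differ from the requested
    proportions by multinomial sampling noise).
    """
    rng = np.random.default_rng(spec.seed)
    mask = _tumor_mask(spec)
    n_in = int(mask.sum())
    codes = np.array([WASHOUT, PLATEAU, PERSISTENT])
    assign = rng.choice(codes, size=n_in, p=np.asarray(spec.class_proportions))

    truth = np.zeros(spec.grid_shape, dtype=np.uint8)
    truth[mask] = assign

    n_phases = 1 + spec.n_post_phases
    stack = np.empty((n_phases,) + tuple(spec.grid_shape), dtype=np.float64)
    bg = simulate_voxel_curve(spec.background, spec.n_post_phases, 0.0)
    stack[:] = bg[:, None, None, None]
    for code, arch in spec.archetypes.items():
        sel = truth == code
        if sel.any():
            curve = simulate_voxel_curve(arch, spec.n_post_phases, 0.0)
            stack[:, sel] = curve[:, None]
    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)

    series = DceSeries(list(stack), spec.voxel_spacing)
    counts = {int(c): int((assign == c).sum()) for c in codes}
    return PhantomResult(
        series, mask, SubregionMap(truth, spec.voxel_spacing), counts
    )


@dataclass
class FeatureCohort:
    """A simulated cohort: feature table, labels, informative columns."""

    table: pd.DataFrame
    labels: np.ndarray
    informative: list[str]


def simulate_feature_cohort(
    spec: CohortSpec, labels: np.ndarray | None = None
) -> FeatureCohort:
    """Draw a patients-by-features table with known informative columns.

    Features are standard normal; the first ``n_informative`` columns are
    shifted by ``feature_effect`` (a standardized mean difference, since
    the noise SD is 1) in the positive class.  Pass ``labels`` to reuse
    one outcome vector across several tables (e.g. to give two ROIs of
    the same patients different effect sizes).
    """
    rng = np.random.default_rng(spec.seed)
    if labels is None:
        labels = (rng.random(spec.n_patients) < spec.prevalence).astype(int)
        # guarantee both classes are present
        if labels.sum() == 0:
            labels[rng.integers(spec.n_patients)] = 1
        elif labels.sum() == spec.n_patients:
            labels[rng.integers(spec.n_patients)] = 0
    else:
        labels = np.asarray(labels, dtype=int)
        if len(labels) != spec.n_patients:
            raise InvalidParameterError("labels length must equal n_patients")

    x = rng.standard_normal((spec.n_patients, spec.n_features))
    x[:, : spec.n_informative] += spec.feature_effect * labels[:, None]
    names = [f"feat_{j:04d}" for j in range(spec.n_features)]
    table = pd.DataFrame(
        x, columns=names, index=[f"patient_{i:04d}" for i in range(spec.n_patients)]
    )
    return FeatureCohort(table, labels, names[: spec.n_informative])
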