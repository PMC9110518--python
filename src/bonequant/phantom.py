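"""Digital SPECT-like phantoms and synthetic cohorts with known truth.

The phantoms emulate reconstructed, SUV-scaled bone SPECT volumes rather
than raw projections: a uniform bone-level background, one or more
ellipsoidal hot lesions (optionally with a cold necrotic core), Gaussian
smoothing standing in for the total system + reconstruction resolution
(default 8 mm FWHM), and optional Poisson-like noise.  The default grid
is 128 x 128 x 64 voxels at 3.90 mm isotropic spacing.

Cohort generation draws per-lesion metabolic bone volumes (MBV) from a
per-stage log-normal (medians 8.28 / 15.28 / 34.61 cm^3 for stages
1/2/3 by default) and lesion-to-background uptake ratios from a
stage-independent log-normal (medians ~ 4.9-5.0), then converts each MBV
draw to a sphere-equivalent lesion.  All randomness flows from one
top-level seed through per-lesion ``numpy.random.SeedSequence``
substreams, so replicates are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import InputError
from .metrics import compute_ratio_metrics, compute_voi_metrics
from .segmentation import (
    ROLE_CONTROL,
    ROLE_LESION_TARGET,
    SeedRegion,
    ThresholdParams,
    define_control_voi,
    segment_lesion_voi,
)
from .volumes import UNITS_SUV_PERCENT, ImageVolume

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.35482...

#: default seed-box margin: target-range half-extents as a multiple of the
#: lesion semi-axes (a snug box drawn around the hot lesion)
DEFAULT_SEED_MARGIN = 1.25


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal hot lesion, optionally with a cold core."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    suv_mean_true: float
    cold_core_fraction: float = 0.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise InputError("lesion semi-axes must be positive")
        if not 0 <= self.cold_core_fraction < 1:
            raise InputError("cold_core_fraction must be in [0, 1)")

    @classmethod
    def sphere(
        cls,
        center_mm: tuple[float, float, float],
        radius_mm: float,
        suv_mean_true: float,
        cold_core_fraction: float = 0.0,
    ) -> "LesionSpec":
        return cls(center_mm, (radius_mm,) * 3, suv_mean_true, cold_core_fraction)


@dataclass
class PhantomSpec:
    """Full description of one synthetic volume."""

    lesions: list[LesionSpec]
    shape: tuple[int, int, int] = (128, 128, 64)
    spacing: tuple[float, float, float] = (3.9, 3.9, 3.9)
    background_suv: float = 1.0
    control_region: SeedRegion | None = None
    blur_fwhm_mm: float = 8.0
    noise: tuple[str, float] | None = None  # ("poisson", scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_fwhm_mm < 0:
            raise InputError("blur_fwhm_mm must be >= 0")
        if self.background_suv < 0:
            raise InputError("background_suv must be >= 0")
        if self.noise is not None:
            kind, scale = self.noise
            if kind != "poisson" or scale <= 0:
                raise InputError("noise must be None or ('poisson', scale > 0)")

    def grid_origin(self) -> tuple[float, float, float]:
        """Origin placing the world origin at the grid center."""
        return tuple(
            -(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing)
        )


@dataclass(frozen=True)
class LesionTruth:
    """Pre-blur ground truth of one lesion."""

    mask: np.ndarray  # hot voxels (cold core excluded)
    volume_cm3: float
    suv_mean_true: float


@dataclass(frozen=True)
class PhantomTruth:
    lesions: tuple[LesionTruth, ...]
    control_true_mean: float


@dataclass(frozen=True)
class CohortSpec:
    """Study-conditions generator for a whole synthetic cohort.

    Defaults mirror the clinical series the package is validated against:
    stage lesion counts (3, 16, 4); per-stage MBV log-normal medians
    8.28 / 15.28 / 34.61 cm^3 with log-sigma 0.4; stage-independent
    lesion-to-control mean-uptake ratios with medians 4.93 / 5.03 / 4.89
    and log-sigma 0.3 (set from the printed stage-1 interquartile range).
    """

    counts: tuple[int, int, int] = (3, 16, 4)
    mbv_medians_cm3: tuple[float, float, float] = (8.28, 15.28, 34.61)
    mbv_sigma: float = 0.4
    rsuv_medians: tuple[float, float, float] = (4.93, 5.03, 4.89)
    rsuv_sigma: float = 0.3
    background_suv: float = 1.0
    blur_fwhm_mm: float = 8.0
    noise: tuple[str, float] | None = ("poisson", 100.0)
    phantom_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (3.9, 3.9, 3.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts):
            raise InputError("per-stage counts must be >= 1")
        if any(m <= 0 for m in self.mbv_medians_cm3 + self.rsuv_medians):
            raise InputError("medians must be positive")


def _ellipsoid_mask(centers: np.ndarray, lesion: LesionSpec, scale: float = 1.0) -> np.ndarray:
    rel = (centers - np.asarray(lesion.center_mm)) / (
        scale * np.asarray(lesion.semi_axes_mm)
    )
    return np.einsum("...i,...i->...", rel, rel) <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Render a phantom volume (SUV units) and its pre-blur ground truth."""
    vol = ImageVolume(
        data=np.full(spec.shape, float(spec.background_suv)),
        spacing=spec.spacing,
        origin=spec.grid_origin(),
        units=UNITS_SUV_PERCENT,
    )
    centers = vol.voxel_centers()
    half_extent = [
        (n - 1) / 2.0 * s for n, s in zip(spec.shape, spec.spacing)
    ]
    truths = []
    data = vol.data
    for lesion in spec.lesions:
        for axis in range(3):
            if (
                abs(lesion.center_mm[axis]) + lesion.semi_axes_mm[axis]
                > half_extent[axis] + spec.spacing[axis] / 2.0
            ):
                raise InputError(
                    f"lesion at {lesion.center_mm} extends outside the grid"
                )
        outer = _ellipsoid_mask(centers, lesion)
        data[outer] = lesion.suv_mean_true
        hot = outer
        if lesion.cold_core_fraction > 0:
            core = _ellipsoid_mask(centers, lesion, scale=lesion.cold_core_fraction)
            data[core] = spec.background_suv
            hot = outer & ~core
        truths.append(
            LesionTruth(
                mask=hot.copy(),
                volume_cm3=float(hot.sum()) * vol.voxel_volume_cm3,
                suv_mean_true=lesion.suv_mean_true,
            )
        )
    if spec.blur_fwhm_mm > 0:
        sigma_vox = [
            spec.blur_fwhm_mm / FWHM_TO_SIGMA / s for s in spec.spacing
        ]
        data = gaussian_filter(data, sigma_vox, mode="nearest")
    if spec.noise is not None:
        _, scale = spec.noise
        rng = np.random.default_rng(spec.seed)
        data = rng.poisson(np.clip(data, 0, None) * scale).astype(float) / scale
    out = vol.with_data(data)
    return out, PhantomTruth(
        lesions=tuple(truths), control_true_mean=float(spec.background_suv)
    )


# -- cohort generation ----------------------------------------------------


def _lesion_phantom_spec(
    radius_mm: float,
    suv_mean_true: float,
    cohort: CohortSpec,
    seed: int,
) -> PhantomSpec:
    """Compact single-lesion phantom: lesion at the grid center, control
    sphere well clear of the lesion's blur tail."""
    control = SeedRegion(
        shape="sphere",
        center_mm=(-65.0, 0.0, 0.0),
        radius_mm=10.0,
        role=ROLE_CONTROL,
    )
    return PhantomSpec(
        lesions=[LesionSpec.sphere((0.0, 0.0, 0.0), radius_mm, suv_mean_true)],
        shape=cohort.phantom_shape,
        spacing=cohort.spacing,
        background_suv=cohort.background_suv,
        control_region=control,
        blur_fwhm_mm=cohort.blur_fwhm_mm,
        noise=cohort.noise,
        seed=seed,
    )


def generate_cohort(
    spec: CohortSpec, with_phantoms: bool = False
) -> tuple[pd.DataFrame, list[PhantomSpec] | None]:
    """Draw a synthetic cohort of ground-truth lesion records.

    Returns a truth table (one row per lesion: stage, true MBV, true
    uptake ratios) and, if ``with_phantoms``, a matching list of
    single-lesion :class:`PhantomSpec` for image-level end-to-end runs.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(sum(spec.counts))
    rows = []
    phantoms: list[PhantomSpec] = []
    idx = 0
    for stage_i, count in enumerate(spec.counts):
        stage = stage_i + 1
        for _ in range(count):
            child = children[idx]
            rng = np.random.default_rng(child)
            mbv = spec.mbv_medians_cm3[stage_i] * np.exp(
                spec.mbv_sigma * rng.standard_normal()
            )
            rsuv = spec.rsuv_medians[stage_i] * np.exp(
                spec.rsuv_sigma * rng.standard_normal()
            )
            radius = (3.0 * mbv * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
            phantom_seed = int(child.generate_state(1)[0] % (2**31))
            rows.append(
                {
                    "patient_id": f"SP{idx + 1:02d}",
                    "lesion_id": f"SL{idx + 1:02d}",
                    "stage": stage,
                    "mbv_cm3": mbv,
                    "rsuv_mean": rsuv,
                    "rsuv_max": rsuv,
                    "rtbu": rsuv * mbv,
                    "radius_mm": radius,
                    "suv_mean_true": spec.background_suv * rsuv,
                    "phantom_seed": phantom_seed,
                }
            )
            if with_phantoms:
                phantoms.append(
                    _lesion_phantom_spec(
                        radius, spec.background_suv * rsuv, spec, phantom_seed
                    )
                )
            idx += 1
    truth = pd.DataFrame(rows)
    return truth, (phantoms if with_phantoms else None)


def recover_and_score(
    phantoms: Sequence[PhantomSpec],
    truth: pd.DataFrame,
    params: ThresholdParams | None = None,
    seed_margin: float = DEFAULT_SEED_MARGIN,
) -> pd.DataFrame:
    """Run the full quantification pipeline on each phantom and score it.

    For every phantom: render the volume, place the target-range box
    (lesion semi-axes x ``seed_margin``), segment the lesion VOI with the
    histogram threshold, measure VOI and ratio metrics against the
    phantom's control region, and report recovered values alongside the
    truth with relative errors.
    """
    params = params or ThresholdParams()
    if len(phantoms) != len(truth):
        raise InputError("phantoms and truth table must have equal length")
    rows = []
    for (_, t), spec in zip(truth.iterrows(), phantoms):
        vol, ptruth = generate_phantom(spec)
        lesion_spec = spec.lesions[0]
        seed_box = SeedRegion(
            shape="box",
            center_mm=lesion_spec.center_mm,
            half_extents_mm=tuple(
                seed_margin * a for a in lesion_spec.semi_axes_mm
            ),
            role=ROLE_LESION_TARGET,
        )
        voi = segment_lesion_voi(vol, seed_box, params)
        lesion_m = compute_voi_metrics(vol, voi)
        control = define_control_voi(vol, spec.control_region)
        control_m = compute_voi_metrics(vol, control)
        ratios = compute_ratio_metrics(lesion_m, control_m)
        true_mbv = ptruth.lesions[0].volume_cm3
        rows.append(
            {
                "lesion_id": t["lesion_id"],
                "stage": t["stage"],
                "true_mbv_cm3": true_mbv,
                "recovered_mbv_cm3": lesion_m.mbv_cm3,
                "mbv_rel_error": (lesion_m.mbv_cm3 - true_mbv) / true_mbv,
                "true_suv_mean": t["suv_mean_true"],
                "recovered_suv_mean": lesion_m.suv_mean,
                "suv_mean_rel_error": (lesion_m.suv_mean - t["suv_mean_true"])
                / t["suv_mean_true"],
                "true_rsuv_mean": t["rsuv_mean"],
                "recovered_rsuv_mean": ratios.rsuv_mean,
                "rsuv_mean_rel_error": (ratios.rsuv_mean - t["rsuv_mean"])
                / t["rsuv_mean"],
                "recovered_rsuv_max": ratios.rsuv_max,
                "true_rtbu": t["rtbu"],
                "recovered_rtbu": ratios.rtbu,
                "rtbu_rel_error": (ratios.rtbu - t["rtbu"]) / t["rtbu"],
                "threshold": voi.threshold_used.threshold,
            }
        )
    return pd.DataFrame(rows)
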