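"""Histogram-threshold VOI segmentation.

The lesion VOI is grown semi-automatically: the user supplies a *target
range* (a world-coordinate box or sphere drawn over the hot lesion), a
threshold is derived from the histogram of the SUVs inside that range,
and the VOI is the 26-connected component of supra-threshold voxels that
contains the hottest voxel of the target range.

Threshold rule
--------------
A histogram with ``n_bins`` uniform bins is built over ``[min, max]`` of
the target-range values.  The *mode* is the center of the most frequent
bin (ties broken toward the lower-value bin).  The *base value* is then,

* ``freq95`` (default): the center of the first bin at or above the modal
  bin whose count has fallen to <= 95% of the modal count (the modal bin
  itself if none has);
* ``value95``: 0.95 x the modal bin center.

and ``threshold = base + sd_multiplier x SD`` with SD the sample standard
deviation of the target-range voxels (default multiplier 0.5).  The
supra-threshold test is closed (``>=``) so a constant target range
segments rather than vanishes.

Control VOIs are purely geometric: every voxel whose center falls inside
the given region, with no thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError, InputError, SegmentationError
from .suv import SUVMap
from .volumes import ImageVolume, MaskVolume

logger = logging.getLogger(__name__)

ROLE_LESION_TARGET = "lesion_target_range"
ROLE_CONTROL = "control"

#: 26-neighbourhood connectivity in 3D
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SeedRegion:
    """A world-coordinate box or sphere used as target range or control.

    ``center_mm`` is the region center in world mm.  Boxes are aligned with
    the world axes and extend ``half_extents_mm`` either side of the
    center; spheres have ``radius_mm``.
    """

    shape: str  # "box" | "sphere"
    center_mm: tuple[float, float, float]
    role: str = ROLE_LESION_TARGET
    half_extents_mm: tuple[float, float, float] | None = None
    radius_mm: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("box", "sphere"):
            raise GeometryError(f"unknown region shape {self.shape!r}")
        if self.role not in (ROLE_LESION_TARGET, ROLE_CONTROL):
            raise GeometryError(f"unknown region role {self.role!r}")
        if self.shape == "box":
            if self.half_extents_mm is None or any(
                h <= 0 for h in self.half_extents_mm
            ):
                raise GeometryError("box region needs positive half_extents_mm")
        else:
            if self.radius_mm is None or self.radius_mm <= 0:
                raise GeometryError("sphere region needs positive radius_mm")

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Boolean membership of world points, shape ``points_mm[..., :3]``."""
        rel = np.asarray(points_mm) - np.asarray(self.center_mm)
        if self.shape == "box":
            return np.all(np.abs(rel) <= np.asarray(self.half_extents_mm), axis=-1)
        return np.einsum("...i,...i->...", rel, rel) <= self.radius_mm**2

    def mask_on(self, vol: ImageVolume | SUVMap) -> np.ndarray:
        """Boolean voxel mask of centers inside the region."""
        return self.contains(vol.voxel_centers())

    @classmethod
    def from_dict(cls, d: dict) -> "SeedRegion":
        """Build from the JSON region schema
        ``{shape, center_mm, radius_mm | half_extents_mm, role}``."""
        kwargs = dict(
            shape=d["shape"],
            center_mm=tuple(float(x) for x in d["center_mm"]),
            role=d.get("role", ROLE_LESION_TARGET),
        )
        if "half_extents_mm" in d and d["half_extents_mm"] is not None:
            kwargs["half_extents_mm"] = tuple(float(x) for x in d["half_extents_mm"])
        if "radius_mm" in d and d["radius_mm"] is not None:
            kwargs["radius_mm"] = float(d["radius_mm"])
        return cls(**kwargs)


@dataclass(frozen=True)
class ThresholdParams:
    """Tunable parameters of the histogram threshold rule."""

    n_bins: int = 128
    sd_multiplier: float = 0.5
    base_rule: str = "freq95"  # "freq95" | "value95"
    sd_scope: str = "target_range"  # "target_range" | "supra_base"
    bin_edges: tuple[float, ...] | None = None  # explicit edges override n_bins

    def __post_init__(self) -> None:
        if self.n_bins < 8:
            raise InputError("n_bins must be >= 8")
        if self.sd_multiplier < 0:
            raise InputError("sd_multiplier must be >= 0")
        if self.base_rule not in ("freq95", "value95"):
            raise InputError(f"unknown base_rule {self.base_rule!r}")
        if self.sd_scope not in ("target_range", "supra_base"):
            raise InputError(f"unknown sd_scope {self.sd_scope!r}")


@dataclass(frozen=True)
class ThresholdEstimate:
    """The derived threshold and the histogram quantities behind it."""

    mode_value: float
    base_value: float
    sd: float
    threshold: float
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass
class VOI:
    """A voxel mask plus the threshold (if any) that produced it."""

    mask: MaskVolume
    role: str  # "lesion" | "control"
    seed: SeedRegion
    threshold_used: ThresholdEstimate | None = None

    @property
    def voxel_count(self) -> int:
        return self.mask.voxel_count


def _sample_sd(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def estimate_threshold(
    values: Sequence[float] | np.ndarray, params: ThresholdParams | None = None
) -> ThresholdEstimate:
    """Derive the segmentation threshold from target-range voxel values."""
    params = params or ThresholdParams()
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise InputError("estimate_threshold: empty target range")

    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        # constant target range: degenerate histogram, zero spread
        edges = np.array([vmin, vmax])
        counts = np.array([values.size])
        return ThresholdEstimate(
            mode_value=vmin,
            base_value=vmin,
            sd=0.0,
            threshold=vmin,
            bin_edges=edges,
            counts=counts,
        )

    if params.bin_edges is not None:
        edges = np.asarray(params.bin_edges, dtype=float)
        counts, edges = np.histogram(values, bins=edges)
    else:
        counts, edges = np.histogram(values, bins=params.n_bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])

    mode_idx = int(np.argmax(counts))  # lowest-value bin on ties
    mode_value = float(centers[mode_idx])
    mode_count = counts[mode_idx]

    if params.base_rule == "freq95":
        base_idx = mode_idx
        for j in range(mode_idx, counts.size):
            if counts[j] <= 0.95 * mode_count:
                base_idx = j
                break
        base_value = float(centers[base_idx])
    else:  # value95
        base_value = 0.95 * mode_value

    if params.sd_scope == "target_range":
        sd = _sample_sd(values)
    else:  # supra_base
        sd = _sample_sd(values[values >= base_value])

    threshold = base_value + params.sd_multiplier * sd
    return ThresholdEstimate(
        mode_value=mode_value,
        base_value=base_value,
        sd=sd,
        threshold=threshold,
        bin_edges=edges,
        counts=counts,
    )


def segment_lesion_voi(
    suv: SUVMap | ImageVolume,
    seed: SeedRegion,
    params: ThresholdParams | None = None,
) -> VOI:
    """Grow the lesion VOI from a target range by histogram thresholding.

    The threshold is estimated from the voxels inside ``seed``; the VOI is
    the 26-connected supra-threshold component containing the
    maximum-value voxel of the seed region.

    Raises
    ------
    SegmentationError
        If no voxel of the seed region reaches the threshold ("empty VOI").
    GeometryError
        If the seed region does not intersect the grid.
    """
    params = params or ThresholdParams()
    if seed.role != ROLE_LESION_TARGET:
        raise InputError(
            f"segment_lesion_voi needs a {ROLE_LESION_TARGET!r} region, got {seed.role!r}"
        )
    in_seed = seed.mask_on(suv)
    if not in_seed.any():
        raise GeometryError("seed region does not intersect the volume grid")
    if suv.data[in_seed].max() <= 0:
        raise SegmentationError("seed region has no uptake (all values <= 0)")

    est = estimate_threshold(suv.data[in_seed], params)
    logger.info(
        "threshold estimate: mode=%.4g base=%.4g sd=%.4g threshold=%.4g",
        est.mode_value,
        est.base_value,
        est.sd,
        est.threshold,
    )
    return grow_voi(suv, seed, est, in_seed=in_seed)


def grow_voi(
    suv: SUVMap | ImageVolume,
    seed: SeedRegion,
    est: ThresholdEstimate,
    in_seed: np.ndarray | None = None,
) -> VOI:
    """Grow the supra-threshold component for a frozen threshold estimate.

    Split out from :func:`segment_lesion_voi` so segmentation can be
    re-run with an attached (frozen) ThresholdEstimate.
    """
    if in_seed is None:
        in_seed = seed.mask_on(suv)
    supra = suv.data >= est.threshold
    if not (supra & in_seed).any():
        raise SegmentationError(
            f"empty VOI: no voxel of the seed region reaches threshold {est.threshold:.4g}"
        )
    # deterministic anchor: maximum-value voxel of the seed region
    seed_vals = np.where(in_seed, suv.data, -np.inf)
    anchor = np.unravel_index(int(np.argmax(seed_vals)), suv.data.shape)
    labels, _ = ndimage.label(supra, structure=_STRUCT_26)
    comp = labels == labels[anchor]
    mask = MaskVolume(
        data=comp,
        spacing=suv.spacing,
        origin=suv.origin,
        orientation=np.asarray(suv.orientation).copy(),
    )
    return VOI(mask=mask, role="lesion", seed=seed, threshold_used=est)


def define_control_voi(suv: SUVMap | ImageVolume, region: SeedRegion) -> VOI:
    """Materialise a manually placed control VOI (no thresholding)."""
    if region.role != ROLE_CONTROL:
        raise InputError(
            f"define_control_voi needs a {ROLE_CONTROL!r} region, got {region.role!r}"
        )
    inside = region.mask_on(suv)
    if not inside.any():
        raise GeometryError("control region lies outside the volume grid")
    mask = MaskVolume(
        data=inside,
        spacing=suv.spacing,
        origin=suv.origin,
        orientation=np.asarray(suv.orientation).copy(),
    )
    return VOI(mask=mask, role="control", seed=region, threshold_used=None)
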