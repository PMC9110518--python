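"""Per-lesion uptake metrics and control-normalised ratios.

* ``SUVmax`` / ``SUVmean`` — maximum / mean SUV over the VOI voxels.
* ``MBV`` (metabolic bone volume, cm^3) — supra-threshold voxel count
  times the voxel volume.  Whole voxels only; no partial-volume weighting.
* ``TBU`` (total bone uptake) — MBV x SUVmean, so TBU is additive over
  disjoint VOI splits.
* ``rSUVmax`` / ``rSUVmean`` — lesion-to-control ratios of SUVmax /
  SUVmean; ``rTBU = rSUVmean x lesion MBV``.

Because the SUV normalisation constant is a single voxelwise scale, the
ratios are identical whether computed on the raw activity volume or the
SUV map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .segmentation import VOI
from .suv import SUVMap
from .volumes import ImageVolume, assert_same_geometry


@dataclass(frozen=True)
class VOIMetrics:
    """Quantitative values of a single VOI."""

    suv_max: float
    suv_mean: float
    mbv_cm3: float
    tbu: float
    voxel_count: int


@dataclass(frozen=True)
class RatioMetrics:
    """Lesion-to-control normalised metrics."""

    rsuv_max: float
    rsuv_mean: float
    rtbu: float


def compute_voi_metrics(suv: SUVMap | ImageVolume, voi: VOI) -> VOIMetrics:
    """Measure SUVmax, SUVmean, MBV and TBU over a VOI.

    Raises
    ------
    InputError
        If the VOI mask is empty.
    GeometryError
        If the mask geometry does not match the volume.
    """
    assert_same_geometry(voi.mask, suv.volume if isinstance(suv, SUVMap) else suv)
    values = suv.data[voi.mask.data]
    if values.size == 0:
        raise InputError("compute_voi_metrics: empty VOI")
    voxel_volume_cm3 = float(np.prod(suv.spacing)) / 1000.0
    mbv = values.size * voxel_volume_cm3
    mean = float(values.mean())
    return VOIMetrics(
        suv_max=float(values.max()),
        suv_mean=mean,
        mbv_cm3=mbv,
        tbu=mbv * mean,
        voxel_count=int(values.size),
    )


def compute_ratio_metrics(lesion: VOIMetrics, control: VOIMetrics) -> RatioMetrics:
    """Normalise lesion metrics by the control VOI.

    Raises
    ------
    InputError
        If the control SUVmax or SUVmean is zero (invalid control VOI).
    """
    if control.suv_max <= 0 or control.suv_mean <= 0:
        raise InputError(
            "invalid control VOI: control SUVmax/SUVmean must be positive "
            f"(got max={control.suv_max}, mean={control.suv_mean})"
        )
    rsuv_mean = lesion.suv_mean / control.suv_mean
    return RatioMetrics(
        rsuv_max=lesion.suv_max / control.suv_max,
        rsuv_mean=rsuv_mean,
        rtbu=rsuv_mean * lesion.mbv_cm3,
    )


def metrics_row(
    patient_id: str,
    lesion_id: str,
    stage: int | None,
    lesion: VOIMetrics,
    ratios: RatioMetrics,
) -> dict:
    """One per-lesion CSV record (column order matters for the pipeline)."""
    return {
        "patient_id": patient_id,
        "lesion_id": lesion_id,
        "stage": stage,
        "suv_max": lesion.suv_max,
        "suv_mean": lesion.suv_mean,
        "mbv_cm3": lesion.mbv_cm3,
        "tbu": lesion.tbu,
        "rsuv_max": ratios.rsuv_max,
        "rsuv_mean": ratios.rsuv_mean,
        "rtbu": ratios.rtbu,
    }
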