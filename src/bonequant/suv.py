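"""Standardized uptake value (SUV) mapping for quantitative bone SPECT.

The SUV of a voxel is its activity concentration normalised by the
administered activity per gram of body weight:

    SUV = pixel [Bq/mL] / (administered activity [Bq] / body weight [g]) x 100 [%]

i.e. an SUV of 100% means the voxel concentrates tracer at exactly the
whole-body average.  The percent scale is the package default; pass
``percent=False`` for the conventional dimensionless g/mL-style SUV
(drops the x100).  Mixing Bq/mL with Bq/g implies a tissue density of
1 g/mL; that assumption is inherited, not corrected.

No decay correction is applied: voxel values are used as reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnitsError
from .volumes import (
    UNITS_ACTIVITY,
    UNITS_DIMENSIONLESS,
    UNITS_SUV_PERCENT,
    AcquisitionMeta,
    ImageVolume,
)


@dataclass
class SUVMap:
    """A body-weight-normalised SUV volume plus its provenance."""

    volume: ImageVolume
    meta: AcquisitionMeta
    percent: bool = True

    # Delegate the geometry surface so an SUVMap can be used anywhere an
    # ImageVolume is expected for read-only purposes.
    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def shape(self):
        return self.volume.shape

    @property
    def spacing(self):
        return self.volume.spacing

    @property
    def origin(self):
        return self.volume.origin

    @property
    def orientation(self):
        return self.volume.orientation

    @property
    def voxel_volume_cm3(self) -> float:
        return self.volume.voxel_volume_cm3

    def voxel_centers(self) -> np.ndarray:
        return self.volume.voxel_centers()


def compute_suv_map(
    volume: ImageVolume, meta: AcquisitionMeta, percent: bool = True
) -> SUVMap:
    """Convert an activity-concentration volume (Bq/mL) to an SUV map.

    Raises
    ------
    UnitsError
        If ``volume.units`` is not ``activity_Bq_per_mL``.
    """
    if volume.units != UNITS_ACTIVITY:
        raise UnitsError(
            f"compute_suv_map expects units {UNITS_ACTIVITY!r}, got {volume.units!r}"
        )
    scale = meta.body_weight_g / meta.administered_activity_bq
    if percent:
        scale *= 100.0
    suv_data = volume.data * scale
    units = UNITS_SUV_PERCENT if percent else UNITS_DIMENSIONLESS
    return SUVMap(volume=volume.with_data(suv_data, units=units), meta=meta, percent=percent)
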