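from __future__ import annotations

import json

import numpy as np
import pytest

from bonequant import (
    AcquisitionMeta,
    ImageVolume,
    SeedRegion,
    write_volume,
)
from bonequant.volumes import UNITS_ACTIVITY


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def meta():
    """Typical acquisition: 740 MBq administered, 60 kg patient."""
    return AcquisitionMeta(
        administered_activity_bq=740e6, body_weight_g=60_000, patient_id="P00"
    )


@pytest.fixture
def activity_volume(rng):
    """Small random activity volume at the default 3.9 mm spacing."""
    data = rng.uniform(0, 20_000, size=(16, 16, 16))
    return ImageVolume(data=data, spacing=(3.9, 3.9, 3.9), units=UNITS_ACTIVITY)


@pytest.fixture
def sphere_phantom_files(tmp_path, meta):
    """A hot-sphere activity volume on disk with sidecar and regions JSON."""
    shape = (32, 32, 32)
    spacing = (3.9, 3.9, 3.9)
    origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, spacing))
    vol = ImageVolume(
        data=np.zeros(shape), spacing=spacing, origin=origin, units=UNITS_ACTIVITY
    )
    centers = vol.voxel_centers()
    r2 = np.sum(centers**2, axis=-1)
    data = np.where(r2 <= 15.0**2, 60_000.0, 2_000.0)
    vol = vol.with_data(data)
    vol_path = tmp_path / "activity.nii.gz"
    write_volume(vol, vol_path)
    meta_path = tmp_path / "meta.json"
    meta_path.write_text(
        json.dumps(
            {
                "administered_activity_bq": meta.administered_activity_bq,
                "body_weight_g": meta.body_weight_g,
                "patient_id": meta.patient_id,
            }
        )
    )
    regions_path = tmp_path / "regions.json"
    regions_path.write_text(
        json.dumps(
            [
                {
                    "shape": "box",
                    "center_mm": [0, 0, 0],
                    "half_extents_mm": [20, 20, 20],
                    "role": "lesion_target_range",
                },
                {
                    "shape": "sphere",
                    "center_mm": [-45, 0, 0],
                    "radius_mm": 10,
                    "role": "control",
                },
            ]
        )
    )
    return {
        "volume": vol_path,
        "meta": meta_path,
        "regions": regions_path,
        "tmp_path": tmp_path,
        "sphere_radius_mm": 15.0,
    }
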