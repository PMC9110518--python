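"""Volumetric image I/O and geometry.

Conventions
-----------
* Voxel indexing is 0-based; ``data[i, j, k]``.
* World coordinates are in millimetres and refer to **voxel centers**:
  ``world = origin + orientation @ (spacing * index)``.
* All region geometry elsewhere in the package is specified in world mm,
  never in voxel indices, so regions are independent of grid resolution.
* Activity volumes are in Bq/mL; SUV maps are in percent (see
  :mod:`bonequant.suv`).

On-disk format is NIfTI-1/NIfTI-2 via nibabel; the acquisition sidecar is
JSON or YAML with keys ``administered_activity_bq``, ``body_weight_g`` and
``patient_id``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import FormatError, GeometryError, MetadataError

logger = logging.getLogger(__name__)

#: recognised units labels
UNITS_ACTIVITY = "activity_Bq_per_mL"
UNITS_SUV_PERCENT = "suv_percent"
UNITS_DIMENSIONLESS = "dimensionless"
VALID_UNITS = (UNITS_ACTIVITY, UNITS_SUV_PERCENT, UNITS_DIMENSIONLESS)

#: absolute tolerance (mm) for spacing/origin comparisons
GEOMETRY_TOL_MM = 1e-4


@dataclass
class ImageVolume:
    """A 3D scalar grid with world geometry and a units label.

    Parameters
    ----------
    data
        3D float array, one value per voxel.
    spacing
        Voxel edge lengths ``(dx, dy, dz)`` in mm, all > 0.
    origin
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    orientation
        3x3 direction matrix mapping index axes to world axes
        (columns are the world directions of the i/j/k axes).
    units
        One of ``activity_Bq_per_mL``, ``suv_percent``, ``dimensionless``.
    n_clamped
        Number of negative voxels clamped to zero at ingestion.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    units: str = UNITS_DIMENSIONLESS
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"expected 3D data, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise GeometryError(f"zero-size grid {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"non-positive spacing {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3):
            raise GeometryError("orientation must be a 3x3 matrix")
        if abs(np.linalg.det(self.orientation)) < 1e-12:
            raise GeometryError("orientation matrix is singular")
        if self.units not in VALID_UNITS:
            raise MetadataError(f"unknown units label {self.units!r}")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->world affine (voxel centers)."""
        aff = np.eye(4)
        aff[:3, :3] = self.orientation @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*grid, 3)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"),
            axis=-1,
        ).astype(float)
        scaled = idx * np.asarray(self.spacing)
        return scaled @ self.orientation.T + np.asarray(self.origin)

    def with_data(self, data: np.ndarray, units: str | None = None) -> "ImageVolume":
        """Copy of this volume with new voxel values (same geometry)."""
        return ImageVolume(
            data=np.asarray(data),
            spacing=self.spacing,
            origin=self.origin,
            orientation=self.orientation.copy(),
            units=self.units if units is None else units,
        )


@dataclass
class MaskVolume:
    """A 3D boolean grid sharing an :class:`ImageVolume`'s geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise GeometryError(f"expected 3D mask, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = np.asarray(self.orientation, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @classmethod
    def like(cls, vol: ImageVolume, data: np.ndarray) -> "MaskVolume":
        return cls(
            data=data,
            spacing=vol.spacing,
            origin=vol.origin,
            orientation=vol.orientation.copy(),
        )


@dataclass(frozen=True)
class AcquisitionMeta:
    """Injection metadata normalising activity to SUV.

    ``administered_activity_bq`` is the administered tracer activity in Bq
    (the packaged fixtures use 740 MBq of a Tc-99m diphosphonate) and
    ``body_weight_g`` the patient body weight in grams.  ``scan_delay_min``
    is recorded for provenance only; voxel values are used as stored, with
    no decay correction.
    """

    administered_activity_bq: float
    body_weight_g: float
    patient_id: str = ""
    scan_delay_min: float | None = None

    def __post_init__(self) -> None:
        for key in ("administered_activity_bq", "body_weight_g"):
            value = getattr(self, key)
            if not np.isfinite(value) or value <= 0:
                raise MetadataError(f"{key} must be a positive number, got {value!r}")


def read_volume(path: str | Path, expected_units: str) -> ImageVolume:
    """Read a NIfTI volume; negatives are clamped to 0 with a logged count.

    The returned volume's geometry comes from the NIfTI affine: spacing is
    the column norms, orientation the normalised columns, origin the
    translation.  ``expected_units`` is attached as the units label (NIfTI
    carries no activity-units field).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        aff = np.asarray(img.affine, dtype=float)
    except Exception as exc:  # nibabel raises several header error types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got shape {data.shape}")
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise GeometryError(f"{path}: degenerate affine (zero spacing)")
    orientation = lin / spacing
    n_neg = int((data < 0).sum())
    if n_neg:
        logger.info("clamped %d negative voxels to 0 in %s", n_neg, path.name)
        data = np.clip(data, 0.0, None)
    return ImageVolume(
        data=data,
        spacing=tuple(spacing),
        origin=tuple(aff[:3, 3]),
        orientation=orientation,
        units=expected_units,
        n_clamped=n_neg,
    )


def write_volume(vol: ImageVolume | MaskVolume, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1 (masks as uint8)."""
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    aff = np.eye(4)
    aff[:3, :3] = np.asarray(vol.orientation) @ np.diag(vol.spacing)
    aff[:3, 3] = vol.origin
    # NIfTI-2: the header stores the affine in doubles, so geometry
    # round-trips exactly (NIfTI-1 would truncate to float32)
    nib.save(nib.Nifti2Image(data, aff), str(path))


_META_ALIASES = {
    "administered_activity_bq": ("administered_activity_bq", "administered_activity"),
    "body_weight_g": ("body_weight_g", "body_weight"),
}


def load_acquisition_meta(path: str | Path) -> AcquisitionMeta:
    """Load and validate the JSON/YAML acquisition sidecar.

    Required keys: ``administered_activity_bq`` (alias
    ``administered_activity``), ``body_weight_g`` (alias ``body_weight``).
    Optional: ``patient_id``, ``scan_delay_min``.
    """
    path = Path(path)
    if not path.exists():
        raise MetadataError(f"no such sidecar: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise MetadataError(f"{path}: sidecar must be a mapping")
    values = {}
    for canonical, aliases in _META_ALIASES.items():
        for alias in aliases:
            if alias in raw:
                values[canonical] = raw[alias]
                break
        else:
            raise MetadataError(f"{path}: missing required key {canonical!r}")
    try:
        return AcquisitionMeta(
            administered_activity_bq=float(values["administered_activity_bq"]),
            body_weight_g=float(values["body_weight_g"]),
            patient_id=str(raw.get("patient_id", "")),
            scan_delay_min=(
                float(raw["scan_delay_min"]) if "scan_delay_min" in raw else None
            ),
        )
    except (TypeError, ValueError) as exc:
        raise MetadataError(f"{path}: {exc}") from exc


def assert_same_geometry(
    a: ImageVolume | MaskVolume,
    b: ImageVolume | MaskVolume,
    tol_mm: float = GEOMETRY_TOL_MM,
) -> None:
    """Raise :class:`GeometryError` naming the first differing geometry field."""
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    if np.max(np.abs(np.subtract(a.spacing, b.spacing))) > tol_mm:
        raise GeometryError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    if np.max(np.abs(np.subtract(a.origin, b.origin))) > tol_mm:
        raise GeometryError(f"origin mismatch: {a.origin} vs {b.origin}")
    if np.max(np.abs(a.orientation - b.orientation)) > tol_mm:
        raise GeometryError("orientation mismatch")
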