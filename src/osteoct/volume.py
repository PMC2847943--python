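"""Voxel volumes, file I/O, region-of-interest geometry and HU-to-BMD calibration.

A :class:`VoxelVolume` is a 3D scalar grid with isotropic spacing, an origin and
a mandatory intensity-unit tag (``"HU"`` or ``"mg_per_cm3"``).  Axis order is
``(z, y, x)`` with z the bone long axis; all physical positions are in mm and
voxel *centers* sit at ``origin + index * spacing`` (node-centered convention).

Cylindrical ROIs follow the MicroView convention used in small-animal bone
densitometry: a "2.5 x 2.5 x 5 mm cylinder" is diameter 2.5 mm x height 5 mm,
axis along z.  A voxel belongs to an ROI iff its center lies inside the
analytic cylinder or box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import SimpleITK as sitk

VALID_UNITS = ("HU", "mg_per_cm3")


@dataclass
class VoxelVolume:
    """Isotropic 3D scalar volume with physical geometry and a unit tag."""

    values: np.ndarray  # (nz, ny, nx)
    spacing: float  # mm, isotropic
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, (z, y, x)
    units: str = "HU"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("volume grid must be a non-empty 3D array")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be > 0 mm, got {self.spacing}")
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units tag {self.units!r}; expected one of {VALID_UNITS}")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates (mm) of voxels along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing * np.arange(n)

    def extent(self, axis: int) -> float:
        """Physical extent (mm) spanned by the voxels along one axis."""
        return self.values.shape[axis] * self.spacing


@dataclass(frozen=True)
class CylinderROI:
    """Axis-aligned (z-axis) cylindrical region of interest; all fields in mm."""

    center_xy: tuple[float, float]  # (y, x)
    z_bottom: float
    height: float
    diameter: float

    def __post_init__(self) -> None:
        if self.height <= 0 or self.diameter <= 0:
            raise ValueError("ROI height and diameter must be positive")

    @property
    def z_top(self) -> float:
        return self.z_bottom + self.height

    def resolve(self, volume: VoxelVolume) -> np.ndarray:
        """Boolean membership mask (voxel-center test) over the volume grid."""
        z = volume.axis_coords(0)
        y = volume.axis_coords(1)
        x = volume.axis_coords(2)
        in_z = (z >= self.z_bottom) & (z <= self.z_top)
        cy, cx = self.center_xy
        r2 = (y[:, None] - cy) ** 2 + (x[None, :] - cx) ** 2
        in_disc = r2 <= (self.diameter / 2.0) ** 2
        mask = in_z[:, None, None] & in_disc[None, :, :]
        if not _roi_inside(volume, self.z_bottom, self.z_top, cy, cx, self.diameter / 2.0):
            raise ValueError(_shortfall_message(volume, self.z_bottom, self.z_top))
        return mask

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "cylinder",
                "center_xy": list(self.center_xy),
                "z_bottom": self.z_bottom,
                "height": self.height,
                "diameter": self.diameter,
            }
        )


@dataclass(frozen=True)
class BoxROI:
    """Axis-aligned rectangular box; center and extents in mm, order (z, y, x)."""

    center: tuple[float, float, float]
    extents: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extents):
            raise ValueError("box extents must be positive")

    def resolve(self, volume: VoxelVolume) -> np.ndarray:
        masks = []
        for axis in range(3):
            c = volume.axis_coords(axis)
            half = self.extents[axis] / 2.0
            masks.append((c >= self.center[axis] - half) & (c <= self.center[axis] + half))
        return masks[0][:, None, None] & masks[1][None, :, None] & masks[2][None, None, :]

    def to_json(self) -> str:
        return json.dumps({"type": "box", "center": list(self.center), "extents": list(self.extents)})


@dataclass(frozen=True)
class CalibrationModel:
    """Affine HU -> mg/cm^3 map fitted to the in-field calibration inserts."""

    slope: float  # (mg/cm^3) per HU
    intercept: float  # mg/cm^3
    fit_r2: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")


@dataclass
class BinaryMask:
    """Segmentation result congruent with its parent volume, with provenance."""

    values: np.ndarray  # bool, parent-shaped
    spacing: float  # mm
    threshold: float
    method: str  # "fixed" | "auto_otsu" | "max_gray_fraction"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)


def _roi_inside(volume, z_bottom, z_top, cy, cx, radius) -> bool:
    z = volume.axis_coords(0)
    y = volume.axis_coords(1)
    x = volume.axis_coords(2)
    return (
        z_bottom >= z[0] - volume.spacing / 2
        and z_top <= z[-1] + volume.spacing / 2
        and cy - radius >= y[0] - volume.spacing / 2
        and cy + radius <= y[-1] + volume.spacing / 2
        and cx - radius >= x[0] - volume.spacing / 2
        and cx + radius <= x[-1] + volume.spacing / 2
    )


def _shortfall_message(volume, z_bottom, z_top) -> str:
    z = volume.axis_coords(0)
    lo = max(0.0, (z[0] - volume.spacing / 2) - z_bottom)
    hi = max(0.0, z_top - (z[-1] + volume.spacing / 2))
    return (
        f"ROI [{z_bottom:.3f}, {z_top:.3f}] mm exits the volume "
        f"(short by {lo:.3f} mm below / {hi:.3f} mm above)"
    )


# ---------------------------------------------------------------------------
# ROI placement anchored to the growth plate
# ---------------------------------------------------------------------------

def place_diaphyseal_roi(volume: VoxelVolume, growth_plate_z: float,
                         center_xy: tuple[float, float] | None = None) -> CylinderROI:
    """Standard diaphyseal measuring cylinder: diameter 2.5 mm, height 5 mm,
    bottom 1.5 mm above the growth plate, centered on the bone axis."""
    if center_xy is None:
        center_xy = _default_axis_center(volume)
    roi = CylinderROI(center_xy=center_xy, z_bottom=growth_plate_z + 1.5,
                      height=5.0, diameter=2.5)
    if not _roi_inside(volume, roi.z_bottom, roi.z_top, *center_xy, roi.diameter / 2):
        raise ValueError(_shortfall_message(volume, roi.z_bottom, roi.z_top))
    return roi


def place_metaphyseal_roi(volume: VoxelVolume, growth_plate_z: float,
                          cortex_inner_radius: float,
                          center_xy: tuple[float, float] | None = None) -> CylinderROI:
    """Metaphyseal trabecular cylinder: diameter 1.5 mm, height 0.6 mm, bottom at
    the growth plate, centered on the bone axis, excluding the cortical shell."""
    if cortex_inner_radius <= 0.75:
        raise ValueError(
            f"metaphyseal ROI (diameter 1.5 mm) does not fit inside the cortex "
            f"(inner radius {cortex_inner_radius:.3f} mm <= 0.75 mm)"
        )
    if center_xy is None:
        center_xy = _default_axis_center(volume)
    roi = CylinderROI(center_xy=center_xy, z_bottom=growth_plate_z, height=0.6, diameter=1.5)
    if not _roi_inside(volume, roi.z_bottom, roi.z_top, *center_xy, roi.diameter / 2):
        raise ValueError(_shortfall_message(volume, roi.z_bottom, roi.z_top))
    return roi


def _default_axis_center(volume: VoxelVolume) -> tuple[float, float]:
    if "axis_center_xy" in volume.metadata:
        return tuple(volume.metadata["axis_center_xy"])
    y = volume.axis_coords(1)
    x = volume.axis_coords(2)
    return (float(y.mean()), float(x.mean()))


def check_roi_clear_of_cortex(roi_mask: np.ndarray, cortex_mask: np.ndarray) -> None:
    n_bad = int(np.count_nonzero(roi_mask & cortex_mask))
    if n_bad:
        raise ValueError(f"ROI intersects the cortical shell in {n_bad} voxels")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def fit_calibration(insert_hu_means, insert_densities) -> CalibrationModel:
    """Ordinary least-squares line density = slope*HU + intercept through the
    calibration-insert means."""
    hu = np.asarray(insert_hu_means, dtype=float)
    rho = np.asarray(insert_densities, dtype=float)
    if hu.size < 2 or rho.size != hu.size:
        raise ValueError("need at least 2 paired insert measurements")
    if np.ptp(hu) == 0:
        raise ValueError("insert HU means are identical; calibration line is undefined")
    slope, intercept = np.polyfit(hu, rho, 1)
    pred = slope * hu + intercept
    ss_res = float(np.sum((rho - pred) ** 2))
    ss_tot = float(np.sum((rho - rho.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationModel(slope=float(slope), intercept=float(intercept), fit_r2=r2)


def apply_calibration(volume: VoxelVolume, model: CalibrationModel,
                      clip_negative: bool = True) -> VoxelVolume:
    """Voxelwise affine HU -> mg/cm^3 map; negative densities are clipped to 0
    (mineral mass density cannot be negative)."""
    if volume.units != "HU":
        raise ValueError(f"volume is already in {volume.units}; refusing double calibration")
    rho = model.slope * volume.values.astype(np.float64) + model.intercept
    if clip_negative:
        rho = np.maximum(rho, 0.0)
    return VoxelVolume(values=rho, spacing=volume.spacing, origin=volume.origin,
                       units="mg_per_cm3", metadata=dict(volume.metadata))


# ---------------------------------------------------------------------------
# File I/O (MetaImage via SimpleITK, NIfTI via nibabel, JSON sidecar for tags)
# ---------------------------------------------------------------------------

def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    path = Path(path)
    name = path.name
    if name.endswith(".mhd"):
        img = sitk.GetImageFromArray(volume.values)
        img.SetSpacing((volume.spacing,) * 3)
        # sitk ordering is (x, y, z)
        img.SetOrigin(tuple(reversed(volume.origin)))
        sitk.WriteImage(img, str(path))
    elif name.endswith((".nii", ".nii.gz")):
        affine = np.diag([volume.spacing] * 3 + [1.0])
        affine[:3, 3] = list(reversed(volume.origin))
        # nibabel expects (x, y, z) data ordering
        nib.save(nib.Nifti1Image(np.ascontiguousarray(volume.values.T), affine), str(path))
    else:
        raise ValueError(f"unsupported volume format: {name} (use .mhd, .nii or .nii.gz)")
    sidecar = {"units": volume.units,
               "metadata": _jsonable(volume.metadata)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_volume(path: str | Path) -> VoxelVolume:
    path = Path(path)
    name = path.name
    if name.endswith(".mhd"):
        img = sitk.ReadImage(str(path))
        spacing = img.GetSpacing()
        values = sitk.GetArrayFromImage(img)
        origin = tuple(reversed(img.GetOrigin()))
    elif name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        spacing = img.header.get_zooms()[:3]
        values = np.asarray(img.dataobj).T
        origin = tuple(reversed(img.affine[:3, 3].tolist()))
    else:
        raise ValueError(f"unsupported volume format: {name}")
    if max(spacing) - min(spacing) > 1e-9:
        raise ValueError(f"anisotropic spacing {spacing} is not supported")
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ValueError(f"units sidecar missing for {path} (expected {sidecar_path.name})")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("units") not in VALID_UNITS:
        raise ValueError(f"unknown or missing units tag in {sidecar_path.name}")
    return VoxelVolume(values=values, spacing=float(spacing[0]), origin=origin,
                       units=sidecar["units"], metadata=sidecar.get("metadata", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
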