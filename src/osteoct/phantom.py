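"""Synthetic femur phantoms with known ground-truth morphometry.

The phantom is a murine distal femur reduced to its measurable essentials:

* a hollow cortical cylinder along z (the diaphysis and the metaphyseal shell),
* a metaphyseal trabecular lattice of parallel plates orthogonal to the bone
  axis plus sparse vertical connecting rods,
* a zero-density growth-plate gap separating metaphysis from epiphysis.

Plates are orthogonal to the bone axis so that the Parfitt plate-model
formulas (TbN = (BV/TV)/TbTh, TbSp = 1/TbN - TbTh) are *exact* on the
generating geometry, which turns parameter recovery into an analytic test.
Each plate is subdivided into angular sectors; the tumor transform removes
whole sectors and jitters the thickness of survivors, producing the
heterogeneous thinning/thickening/loss pattern seen in osteoblastic prostate
cancer models, together with inward cortical thickening of the shaft.

Scanning is modelled as block averaging to the target voxel size (the
partial-volume effect that dominates mouse trabecular uCT), a linear
density-to-HU map, additive Gaussian noise, and a two-density calibration
insert appended inside the field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .volume import VoxelVolume

# ---------------------------------------------------------------------------
# Generative specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and material densities of one synthetic femur.

    Lengths are mm except the trabecular scale and base voxel, which are um;
    densities are mg/cm^3 of mineral.
    """

    bone_length: float = 9.0
    outer_radius: float = 1.2
    cortical_thickness: float = 0.25
    trabecular_thickness: float = 40.0  # um
    trabecular_spacing: float = 220.0  # um
    lattice_orientation: tuple[float, float, float] = (1.0, 0.0, 0.0)  # (z, y, x)
    density_cortex: float = 1200.0
    density_trabecula: float = 1000.0
    density_marrow: float = 30.0  # mineral-equivalent density of marrow tissue
    growth_plate_z: float = 2.0  # distance of the growth plate from the distal end
    base_voxel: float = 8.0  # um
    seed: int = 0
    # secondary geometry (defaults emulate a mouse distal femur)
    metaphysis_length: float = 1.2
    growth_plate_gap: float = 0.12
    n_sectors: int = 6
    rod_radius_factor: float = 0.5  # rod radius as a fraction of plate thickness
    rod_pitch: float = 0.45
    xy_margin: float = 0.11

    def __post_init__(self) -> None:
        if self.base_voxel > self.trabecular_thickness / 4:
            raise ValueError(
                "base_voxel must satisfy base_voxel <= trabecular_thickness / 4 "
                f"(got {self.base_voxel} um vs {self.trabecular_thickness} um trabeculae)"
            )
        if not self.cortical_thickness < self.outer_radius:
            raise ValueError("cortical_thickness must be smaller than outer_radius")
        if min(self.density_cortex, self.density_trabecula, self.density_marrow) < 0:
            raise ValueError("densities must be non-negative")
        if not 0 < self.growth_plate_z < self.bone_length:
            raise ValueError("growth_plate_z must lie inside the bone")
        axis = np.asarray(self.lattice_orientation, dtype=float)
        axis = axis / np.linalg.norm(axis)
        if abs(abs(axis[0]) - 1.0) > 1e-6:
            raise ValueError("only lattices oriented along the bone (z) axis are supported")

    @property
    def period_mm(self) -> float:
        return (self.trabecular_thickness + self.trabecular_spacing) / 1000.0

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.cortical_thickness

    @property
    def expected_tbn(self) -> float:
        """Plates crossed per mm along the bone axis for the pristine lattice."""
        return 1.0 / self.period_mm


@dataclass(frozen=True)
class TumorEffect:
    """Net osteoblastic/osteolytic transform applied to the tumor-bearing femur.

    Besides removing/jittering trabecular elements and thickening the cortex,
    tumor infiltration raises the apparent density of the marrow space (soft
    tissue replacing fatty marrow); the realized shift varies between animals
    (lognormal, ``marrow_shift_jitter_sd``), which is what destabilizes
    histogram-derived automatic thresholds in diseased bone.
    """

    cortical_thickening_factor: float = 1.35
    trabecular_removal_fraction: float = 0.4
    thickness_jitter_sd: float = 0.2  # lognormal sigma, multiplicative per element
    marrow_density_shift: float = 30.0  # mg/cm^3 equivalent, median
    marrow_shift_jitter_sd: float = 0.6  # lognormal sigma across animals
    mineralization_factor: float = 0.85  # surviving trabeculae (woven bone/osteoid)
    mineralization_jitter_sd: float = 0.1  # lognormal sigma across animals
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cortical_thickening_factor < 1:
            raise ValueError("cortical_thickening_factor must be >= 1")
        if not 0 <= self.trabecular_removal_fraction <= 1:
            raise ValueError("trabecular_removal_fraction must lie in [0, 1]")
        if self.thickness_jitter_sd < 0 or self.marrow_shift_jitter_sd < 0 \
                or self.mineralization_jitter_sd < 0:
            raise ValueError("jitter SDs must be >= 0")
        if self.marrow_density_shift < 0:
            raise ValueError("marrow_density_shift must be >= 0")
        if not 0 < self.mineralization_factor <= 1:
            raise ValueError("mineralization_factor must lie in (0, 1]")


@dataclass(frozen=True)
class ScannerModel:
    """Linear acquisition model: block averaging, HU map, noise, inserts."""

    voxel_size: float  # um
    hu_gain: float  # HU per (mg/cm^3)
    hu_offset: float = 0.0
    noise_sd: float = 0.0  # HU
    insert_densities: tuple[float, ...] = (0.0, 1000.0)
    name: str = "scanner"

    def __post_init__(self) -> None:
        if self.hu_gain <= 0:
            raise ValueError("hu_gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_scanners() -> dict[str, ScannerModel]:
    """The four resolution classes of the study design.

    Nominal in vivo 91 um and ex vivo 31/16/8 um acquisitions are realized at
    88/32/16/8 um so every scan is an integer block average of the 8 um
    phantom grid.  The ex vivo specimen scanner reports HU on a hotter scale
    (gain 2.2x the in vivo scanner), which is what makes the two threshold
    regimes (hundreds vs thousands of HU) distinct.
    """
    # noise grows as voxels shrink (photon statistics); HU scale differs per scanner
    return {
        "invivo91": ScannerModel(voxel_size=88.0, hu_gain=1.0, noise_sd=40.0, name="invivo91"),
        "exvivo31": ScannerModel(voxel_size=32.0, hu_gain=2.2, noise_sd=80.0, name="exvivo31"),
        "exvivo16": ScannerModel(voxel_size=16.0, hu_gain=2.2, noise_sd=120.0, name="exvivo16"),
        "exvivo8": ScannerModel(voxel_size=8.0, hu_gain=2.2, noise_sd=200.0, name="exvivo8"),
    }


@dataclass
class GroundTruth:
    """True morphometry of the constructed (or tumor-transformed) geometry."""

    bvtv_metaphysis: float
    tbn: float  # /mm
    tbth: float  # mm
    tbsp: float  # mm
    mean_density_metaphysis: float  # mg/cm^3
    bvtv_diaphysis: float
    mean_density_diaphysis: float  # mg/cm^3
    cortical_thickness: float  # mm
    inner_radius: float  # mm
    n_elements: int
    n_removed: int = 0


# ---------------------------------------------------------------------------
# Lattice elements
# ---------------------------------------------------------------------------


@dataclass
class _Element:
    kind: str  # "plate" | "rod"
    plate_index: int
    sector: int  # -1 for rods
    z_center: float  # mm (plates)
    thickness: float  # mm (plate thickness or rod diameter)
    center_xy: tuple[float, float] = (0.0, 0.0)  # rods only
    present: bool = True


def _make_elements(spec: PhantomSpec) -> list[_Element]:
    """Plate sectors with per-sector phase stagger plus connecting rods.

    Each angular sector's plate stack is shifted by s/n_sectors of a period
    along z, so any axial window samples the lattice at n_sectors phases and
    finite-window volume fractions are unbiased (no fencepost artifact).
    """
    elements: list[_Element] = []
    period = spec.period_mm
    tbth = spec.trabecular_thickness / 1000.0
    # one buffer period of primary spongiosa below the ROI anchor, so the
    # standard metaphyseal window samples the lattice from its interior
    z0 = spec.growth_plate_z - period
    span = spec.metaphysis_length + period
    phase_max = period * (spec.n_sectors - 1) / spec.n_sectors
    n_plates = int(math.floor((span - tbth - phase_max) / period)) + 1
    for k in range(n_plates):
        for s in range(spec.n_sectors):
            phase = period * s / spec.n_sectors
            zc = z0 + phase + k * period + tbth / 2.0
            elements.append(_Element("plate", k, s, zc, tbth))
    rod_d = 2 * spec.rod_radius_factor * tbth
    pitch = spec.rod_pitch
    reach = spec.inner_radius - rod_d
    # half-pitch offset keeps rod axes off the mid-sagittal plane, so thin
    # sections do not run along a rod
    n_side = int(math.ceil(reach / pitch))
    for iy in range(-n_side, n_side):
        for ix in range(-n_side, n_side):
            cy, cx = (iy + 0.5) * pitch, (ix + 0.5) * pitch
            if math.hypot(cy, cx) <= reach:
                elements.append(_Element("rod", -1, -1, 0.0, rod_d, (cy, cx)))
    return elements


# ---------------------------------------------------------------------------
# Painting and measuring
# ---------------------------------------------------------------------------


def _grid_geometry(spec: PhantomSpec):
    sp = spec.base_voxel / 1000.0  # mm
    half_xy = max(spec.outer_radius, 1.25) + spec.xy_margin
    n_xy = int(round(2 * half_xy / sp))
    nz = int(round(spec.bone_length / sp))
    origin = (0.0, -(n_xy - 1) / 2.0 * sp, -(n_xy - 1) / 2.0 * sp)
    return sp, nz, n_xy, origin


def _paint(spec: PhantomSpec, elements: Sequence[_Element], inner_radius: float,
           marrow_density: float | None = None,
           trabecula_density: float | None = None) -> VoxelVolume:
    sp, nz, n_xy, origin = _grid_geometry(spec)
    z = origin[0] + sp * np.arange(nz)
    yx = origin[1] + sp * np.arange(n_xy)
    r2 = yx[:, None] ** 2 + yx[None, :] ** 2
    angle = np.arctan2(yx[:, None], yx[None, :])  # (-pi, pi]

    marrow = spec.density_marrow if marrow_density is None else marrow_density
    rho_trab = spec.density_trabecula if trabecula_density is None else trabecula_density
    values = np.zeros((nz, n_xy, n_xy), dtype=np.float32)  # air outside the bone

    # cortical shell, full bone length
    shell = (r2 <= spec.outer_radius**2) & (r2 > inner_radius**2)
    values[:, shell] = spec.density_cortex

    interior = r2 <= inner_radius**2
    if marrow != 0.0:
        values[:, interior] = np.float32(marrow)

    # interior compartments along z: growth-plate gap below the lattice span
    lat_lo = spec.growth_plate_z - spec.period_mm
    gp_lo = lat_lo - spec.growth_plate_gap
    meta_hi = spec.growth_plate_z + spec.metaphysis_length
    # zero-density growth plate gap across the interior
    gap_idx = np.flatnonzero((z >= gp_lo) & (z < lat_lo))
    if gap_idx.size:
        sub = values[gap_idx[0] : gap_idx[-1] + 1]
        sub[:, interior] = 0.0

    # trabecular marrow space starts as marrow; paint surviving elements
    sector_of = np.floor((angle + np.pi) / (2 * np.pi / spec.n_sectors)).astype(np.int32)
    sector_of = np.clip(sector_of, 0, spec.n_sectors - 1)

    for el in elements:
        if not el.present:
            continue
        if el.kind == "plate":
            z_lo, z_hi = el.z_center - el.thickness / 2.0, el.z_center + el.thickness / 2.0
            zi = np.flatnonzero((z >= z_lo) & (z < z_hi) & (z < meta_hi) & (z >= lat_lo))
            if zi.size == 0:
                continue
            mask2d = interior & (sector_of == el.sector)
            sub = values[zi[0] : zi[-1] + 1]
            sub[:, mask2d] = rho_trab
        else:  # rod
            cy, cx = el.center_xy
            rod2 = (yx[:, None] - cy) ** 2 + (yx[None, :] - cx) ** 2
            mask2d = (rod2 <= (el.thickness / 2.0) ** 2) & interior
            zi = np.flatnonzero((z >= lat_lo) & (z < meta_hi))
            if zi.size == 0 or not mask2d.any():
                continue
            sub = values[zi[0] : zi[-1] + 1]
            sub[:, mask2d] = rho_trab

    vol = VoxelVolume(
        values=values,
        spacing=sp,
        origin=origin,
        units="mg_per_cm3",
        metadata={
            "axis_center_xy": (0.0, 0.0),
            "growth_plate_z": spec.growth_plate_z,
            "base_resolution": True,
        },
    )
    return vol


def _realized_thickness(spec: PhantomSpec, el: _Element) -> float:
    """Plate thickness as realized on the voxel grid (z-voxel count x spacing)."""
    sp, nz, _, origin = _grid_geometry(spec)
    z = origin[0] + sp * np.arange(nz)
    lat_lo = spec.growth_plate_z - spec.period_mm
    meta_hi = spec.growth_plate_z + spec.metaphysis_length
    z_lo, z_hi = el.z_center - el.thickness / 2.0, el.z_center + el.thickness / 2.0
    n = int(np.count_nonzero((z >= z_lo) & (z < z_hi) & (z < meta_hi) & (z >= lat_lo)))
    return n * sp


def _measure_truth(spec: PhantomSpec, volume: VoxelVolume, elements: Sequence[_Element],
                   inner_radius: float, cortical_thickness: float, n_removed: int,
                   bone_cut: float | None = None) -> GroundTruth:
    sp = volume.spacing
    z = volume.axis_coords(0)
    yx = volume.axis_coords(1)
    r2 = yx[:, None] ** 2 + yx[None, :] ** 2

    # metaphyseal trabecular compartment: the 1.5 x 0.6 mm measurement cylinder
    gp = spec.growth_plate_z
    zi = np.flatnonzero((z >= gp) & (z <= gp + 0.6))
    disc = r2 <= 0.75**2
    if bone_cut is None:
        bone_cut = min(spec.density_trabecula, spec.density_cortex) * 0.5
    region = volume.values[zi[0] : zi[-1] + 1][:, disc]
    bone = region >= bone_cut
    bvtv_meta = float(np.count_nonzero(bone)) / region.size
    mean_rho_meta = float(region.mean(dtype=np.float64))

    # diaphyseal compartment: the 2.5 x 5 mm measurement cylinder
    zi_d = np.flatnonzero((z >= gp + 1.5) & (z <= gp + 6.5))
    disc_d = r2 <= 1.25**2
    region_d = volume.values[zi_d[0] : zi_d[-1] + 1][:, disc_d]
    bone_d = region_d >= spec.density_cortex * 0.5
    bvtv_dia = float(np.count_nonzero(bone_d)) / region_d.size
    mean_rho_dia = float(region_d.mean(dtype=np.float64))

    # plate-model truth from surviving elements
    plates = [el for el in elements if el.kind == "plate" and el.present]
    n_sectors = spec.n_sectors
    if plates:
        # expected plate crossings per mm along a random vertical line through
        # the lattice cell (K periods per sector stack)
        n_periods = max(el.plate_index for el in elements if el.kind == "plate") + 1
        tbn = len(plates) / (n_sectors * n_periods * spec.period_mm)
        th = np.array([_realized_thickness(spec, el) for el in plates])
        tbth = float(np.average(th, weights=th))  # volume-weighted
        tbsp = 1.0 / tbn - tbth
    else:
        tbn, tbth = 0.0, 0.0
        tbsp = spec.metaphysis_length

    return GroundTruth(
        bvtv_metaphysis=bvtv_meta,
        tbn=tbn,
        tbth=tbth,
        tbsp=tbsp,
        mean_density_metaphysis=mean_rho_meta,
        bvtv_diaphysis=bvtv_dia,
        mean_density_diaphysis=mean_rho_dia,
        cortical_thickness=cortical_thickness,
        inner_radius=inner_radius,
        n_elements=len(elements),
        n_removed=n_removed,
    )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def build_femur_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Generate the base-resolution density volume and its exact ground truth."""
    elements = _make_elements(spec)
    volume = _paint(spec, elements, spec.inner_radius)
    volume.metadata["elements"] = elements
    volume.metadata["spec"] = spec
    truth = _measure_truth(spec, volume, elements, spec.inner_radius,
                           spec.cortical_thickness, n_removed=0)
    return volume, truth


def apply_tumor_effect(volume: VoxelVolume, truth: GroundTruth,
                       effect: TumorEffect) -> tuple[VoxelVolume, GroundTruth]:
    """Apply sector-wise trabecular removal/jitter and cortical thickening.

    Operates only on a base-resolution phantom; the transformed volume is
    repainted from the surviving element list, so the returned truth reflects
    the realized geometry, not the expectation.
    """
    if not volume.metadata.get("base_resolution", False):
        raise ValueError("tumor effect must be applied at base resolution, before scanning")
    spec: PhantomSpec = volume.metadata["spec"]
    elements: list[_Element] = volume.metadata["elements"]

    rng = np.random.default_rng(effect.seed)
    new_elements: list[_Element] = []
    n_removed = 0
    for el in elements:
        removed = bool(rng.random() < effect.trabecular_removal_fraction)
        jitter = float(np.exp(rng.normal(0.0, effect.thickness_jitter_sd))) \
            if effect.thickness_jitter_sd > 0 else 1.0
        if removed:
            n_removed += 1
            new_elements.append(replace(el, present=False))
        else:
            new_elements.append(replace(el, thickness=el.thickness * jitter))

    new_ct = spec.cortical_thickness * effect.cortical_thickening_factor
    if new_ct >= spec.outer_radius:
        raise ValueError("cortical thickening factor collapses the marrow cavity")
    new_inner = spec.outer_radius - new_ct

    marrow = spec.density_marrow
    if effect.marrow_density_shift > 0:
        marrow = marrow + effect.marrow_density_shift * float(
            np.exp(rng.normal(0.0, effect.marrow_shift_jitter_sd)))
    mineral = min(1.0, effect.mineralization_factor * float(
        np.exp(rng.normal(0.0, effect.mineralization_jitter_sd)))) \
        if effect.mineralization_factor < 1 else 1.0
    rho_trab = spec.density_trabecula * mineral

    out = _paint(spec, new_elements, new_inner, marrow_density=marrow,
                 trabecula_density=rho_trab)
    out.metadata["elements"] = new_elements
    out.metadata["spec"] = spec
    out.metadata["tumor_effect"] = effect
    out.metadata["realized_trabecula_density"] = rho_trab
    new_truth = _measure_truth(spec, out, new_elements, new_inner, new_ct, n_removed,
                               bone_cut=0.5 * min(rho_trab, spec.density_cortex))
    return out, new_truth


def simulate_scan(volume: VoxelVolume, scanner: ScannerModel, seed: int | None = None,
                  fov_z: tuple[float, float] | None = None,
                  fov_xy_half: float | None = None) -> VoxelVolume:
    """Block-average to the scanner voxel size, map to HU, add noise, append inserts.

    ``fov_z``/``fov_xy_half`` optionally restrict the field of view (in mm)
    before resampling, emulating the limited coverage of the finest ex vivo
    acquisition.
    """
    if volume.units != "mg_per_cm3":
        raise ValueError("simulate_scan expects a density (mg/cm^3) volume")
    sp_um = volume.spacing * 1000.0
    ratio = scanner.voxel_size / sp_um
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-6 or factor < 1:
        raise ValueError(
            f"scanner voxel size {scanner.voxel_size} um is not an integer multiple "
            f"of the volume spacing {sp_um:g} um"
        )

    vals = volume.values
    origin = list(volume.origin)
    sp = volume.spacing
    # optional FOV crop
    if fov_z is not None:
        z = volume.axis_coords(0)
        keep = np.flatnonzero((z >= fov_z[0]) & (z <= fov_z[1]))
        vals = vals[keep[0] : keep[-1] + 1]
        origin[0] = float(z[keep[0]])
    if fov_xy_half is not None:
        for axis in (1, 2):
            c = origin[axis] + sp * np.arange(vals.shape[axis])
            keep = np.flatnonzero(np.abs(c) <= fov_xy_half)
            sl = [slice(None)] * 3
            sl[axis] = slice(keep[0], keep[-1] + 1)
            vals = vals[tuple(sl)]
            origin[axis] = float(c[keep[0]])

    # crop so every axis is a multiple of the block factor: z keeps the distal
    # end, x/y are trimmed symmetrically to keep the bone axis centered
    rem_z = vals.shape[0] % factor
    vals = vals[: vals.shape[0] - rem_z] if rem_z else vals
    for axis in (1, 2):
        rem = vals.shape[axis] % factor
        if rem:
            lo = rem // 2
            sl = [slice(None)] * 3
            sl[axis] = slice(lo, vals.shape[axis] - (rem - lo))
            vals = vals[tuple(sl)]
            origin[axis] += lo * sp
    nz, ny, nx = vals.shape
    blocks = vals.reshape(nz // factor, factor, ny // factor, factor, nx // factor, factor)
    rho = blocks.mean(axis=(1, 3, 5), dtype=np.float64)

    hu = scanner.hu_gain * rho + scanner.hu_offset

    # calibration insert: a band appended on the +y side, one segment per density
    band_w = max(2, int(round(0.4 / (sp * factor))))
    gap = 1
    nz2, ny2, nx2 = hu.shape
    assembled = np.full((nz2, ny2 + gap + band_w, nx2),
                        scanner.hu_gain * 0.0 + scanner.hu_offset, dtype=np.float64)
    assembled[:, :ny2, :] = hu
    inserts = []
    n_ins = len(scanner.insert_densities)
    seg = nz2 // n_ins
    for i, d in enumerate(scanner.insert_densities):
        z0, z1 = i * seg, (i + 1) * seg if i < n_ins - 1 else nz2
        assembled[z0:z1, ny2 + gap :, :] = scanner.hu_gain * d + scanner.hu_offset
        inserts.append({"density": float(d),
                        "index_ranges": [[int(z0), int(z1)], [int(ny2 + gap), int(ny2 + gap + band_w)],
                                          [0, int(nx2)]]})

    if scanner.noise_sd > 0:
        rng = np.random.default_rng(seed)
        assembled = assembled + scanner.noise_sd * rng.standard_normal(assembled.shape)

    new_spacing = sp * factor
    new_origin = (origin[0] + (factor - 1) / 2.0 * sp,
                  origin[1] + (factor - 1) / 2.0 * sp,
                  origin[2] + (factor - 1) / 2.0 * sp)
    meta = {k: v for k, v in volume.metadata.items() if k not in ("elements", "spec")}
    meta.update({
        "base_resolution": False,
        "scanner": scanner.name,
        "voxel_size_um": scanner.voxel_size,
        "hu_gain": scanner.hu_gain,
        "hu_offset": scanner.hu_offset,
        "calibration_inserts": inserts,
    })
    return VoxelVolume(values=assembled, spacing=new_spacing, origin=new_origin,
                       units="HU", metadata=meta)


def insert_hu_means(volume: VoxelVolume) -> tuple[list[float], list[float]]:
    """Mean HU and nominal density of each calibration-insert region."""
    inserts = volume.metadata.get("calibration_inserts")
    if not inserts:
        raise ValueError("volume has no recorded calibration inserts")
    means, densities = [], []
    for ins in inserts:
        (z0, z1), (y0, y1), (x0, x1) = ins["index_ranges"]
        means.append(float(volume.values[z0:z1, y0:y1, x0:x1].mean(dtype=np.float64)))
        densities.append(ins["density"])
    return means, densities


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Specimen:
    """One femur of one animal: a jittered spec plus (for tumor sides) an effect."""

    animal_id: int
    side: str  # "left" (vehicle) | "right" (tumor)
    spec: PhantomSpec
    effect: TumorEffect | None

    def build(self) -> tuple[VoxelVolume, GroundTruth]:
        volume, truth = build_femur_phantom(self.spec)
        if self.effect is not None:
            volume, truth = apply_tumor_effect(volume, truth, self.effect)
        return volume, truth

    @property
    def expected_tbn(self) -> float:
        return self.spec.expected_tbn


def make_cohort(n_animals: int, spec: PhantomSpec | None = None,
                effect: TumorEffect | None = None, master_seed: int = 0,
                biological_cv: float = 0.08, density_cv: float = 0.03,
                marrow_cv: float = 0.3) -> list[Specimen]:
    """Paired left (vehicle) / right (tumor) femora with per-animal biology.

    Per-animal multiplicative lognormal jitter is applied to the trabecular
    scale and cortical thickness (sigma = ``biological_cv``) and to the
    material densities (sigma = ``density_cv``; tissue mineralization is much
    more tightly regulated than architecture).  Basal marrow density varies
    per femur (sigma = ``marrow_cv``; red/yellow marrow composition is local),
    which is the main driver of histogram-derived threshold variability in
    healthy bone.  Both femora of an animal share the jittered anatomy, and
    all randomness derives deterministically from ``master_seed``.
    """
    if n_animals < 2:
        raise ValueError("need at least 2 animals for paired statistics")
    if spec is None:
        spec = PhantomSpec()
    if effect is None:
        effect = TumorEffect()
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_animals)
    cohort: list[Specimen] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        j = lambda cv: float(np.exp(rng.normal(0.0, cv)))  # noqa: E731
        animal_spec = replace(
            spec,
            # clamp so the jittered lattice stays resolvable on the base grid
            trabecular_thickness=max(spec.trabecular_thickness * j(biological_cv),
                                     4.0 * spec.base_voxel),
            trabecular_spacing=spec.trabecular_spacing * j(biological_cv),
            cortical_thickness=spec.cortical_thickness * j(biological_cv),
            density_cortex=spec.density_cortex * j(density_cv),
            density_trabecula=spec.density_trabecula * j(density_cv),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        animal_effect = replace(effect, seed=int(rng.integers(0, 2**31 - 1)))
        left_spec = replace(animal_spec, density_marrow=spec.density_marrow * j(marrow_cv))
        right_spec = replace(animal_spec, density_marrow=spec.density_marrow * j(marrow_cv))
        cohort.append(Specimen(i, "left", left_spec, None))
        cohort.append(Specimen(i, "right", right_spec, animal_effect))
    return cohort
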