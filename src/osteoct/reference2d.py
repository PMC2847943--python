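"""Emulated 2D reference modalities: Von-Kossa histomorphometry and DXA.

Histomorphometry is modelled as perfect binarization of thin sagittal
sections at base resolution (the mineral stain is treated as noiseless, as
befits a reference standard), followed by line-intercept stereology along
the bone axis.  DXA is a noiseless monoenergetic line-integral projection
along the mediolateral axis, which by construction cannot separate
trabecular from cortical mineral on the same ray.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import VoxelVolume


@dataclass
class Rect2D:
    """Rectangle in a sagittal (z, y) plane; center and extents in mm."""

    center: tuple[float, float]  # (z, y)
    extents: tuple[float, float]  # (z, y)

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extents):
            raise ValueError("rect extents must be positive")


@dataclass
class SectionImage:
    """One binarized sagittal section: (z, y) boolean pixel grid."""

    image: np.ndarray  # bool (nz, ny)
    pixel_size: float  # mm
    level: str  # right | mid | left
    x_offset: float  # mm from the bone axis
    origin: tuple[float, float] = (0.0, 0.0)  # (z, y) of pixel (0, 0)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.pixel_size * np.arange(self.image.shape[axis])


@dataclass
class HistoResult:
    """Per-section and three-section-mean intercept morphometry."""

    bvtv: float
    tbn: float  # /mm
    tbsp: float  # mm
    tbth: float  # mm
    per_section: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class DxaResult:
    areal_bmd: float  # g/cm^2
    rect: Rect2D
    projection_axis: int = 2  # x, mediolateral


# ---------------------------------------------------------------------------


def extract_sections(volume: VoxelVolume, levels: dict[str, float] | None = None,
                     mineral_density_cut: float = 500.0) -> list[SectionImage]:
    """Binarized single-voxel-plane sagittal sections at three x-offsets.

    Default levels sit at -25%, 0 and +25% of the bone width from the axis
    (the ``right``/``mid``/``left`` sampling of standard three-level
    histology).  Offsets must lie strictly inside the bone.
    """
    if volume.units != "mg_per_cm3":
        raise ValueError("sections are cut from the density (mg/cm^3) phantom")
    x = volume.axis_coords(2)
    cy, cx = volume.metadata.get("axis_center_xy", (0.0, 0.0))
    if levels is None:
        spec = volume.metadata.get("spec")
        half_width = spec.outer_radius if spec is not None else 0.25 * (x[-1] - x[0])
        levels = {"right": -0.5 * half_width, "mid": 0.0, "left": 0.5 * half_width}
        bone_half = half_width
    else:
        spec = volume.metadata.get("spec")
        bone_half = spec.outer_radius if spec is not None else np.inf
    sections = []
    for name, off in levels.items():
        if abs(off) >= bone_half:
            raise ValueError(f"section offset {off} mm lies outside the bone (half-width {bone_half} mm)")
        ix = int(np.argmin(np.abs(x - (cx + off))))
        img = volume.values[:, :, ix] >= mineral_density_cut
        sections.append(SectionImage(image=img, pixel_size=volume.spacing, level=name,
                                     x_offset=off, origin=(volume.origin[0], volume.origin[1])))
    return sections


def _line_runs(line: np.ndarray) -> list[tuple[bool, int, bool]]:
    """Run-length encode a boolean test line: (value, length, touches_edge)."""
    n = line.size
    change = np.flatnonzero(line[1:] != line[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return [(bool(line[s]), int(e - s), s == 0 or e == n)
            for s, e in zip(starts, ends)]


def histo_intercepts(rect_pixels: np.ndarray, pixel_size: float) -> dict[str, float]:
    """Line-intercept stereology along axis 0 (the bone axis) of a 2D window.

    Test lines run along every pixel column.  Runs touching the window edge
    are discarded from the thickness/separation means and from the intercept
    count -- except a run spanning the entire line, which counts as one
    intercept of full length (the degenerate all-bone / all-marrow case).
    TbN is the number of counted bone intercepts per mm of test line.
    """
    nz, ny = rect_pixels.shape
    if ny == 0 or nz == 0:
        raise ValueError("window contains no test lines")
    bone_lengths: list[int] = []
    marrow_lengths: list[int] = []
    n_intercepts = 0
    for j in range(ny):
        for value, length, edge in _line_runs(rect_pixels[:, j]):
            whole_line = length == nz
            if edge and not whole_line:
                continue
            if value:
                bone_lengths.append(length)
                n_intercepts += 1
            else:
                marrow_lengths.append(length)
    total_line = ny * nz * pixel_size  # mm of test line
    tbn = n_intercepts / total_line
    tbth = float(np.mean(bone_lengths)) * pixel_size if bone_lengths else 0.0
    tbsp_icpt = float(np.mean(marrow_lengths)) * pixel_size if marrow_lengths else 0.0
    # separation is reported in the derived (plate) form, which unlike the raw
    # mean marrow intercept is not capped by the window height
    tbsp = max(1.0 / tbn - tbth, 0.0) if tbn > 0 else tbsp_icpt
    return {
        "BVTV": float(np.count_nonzero(rect_pixels)) / rect_pixels.size,
        "TbN": tbn,
        "TbTh": tbth,
        "TbSp": tbsp,
        "TbSp_intercept": tbsp_icpt,
    }


def histo_morphometry(sections: list[SectionImage], site_rect: Rect2D,
                      per_level_rects: dict[str, Rect2D] | None = None) -> HistoResult:
    """Intercept morphometry of a rectangular window, averaged over sections.

    ``per_level_rects`` overrides the window per section level -- used to clip
    the metaphyseal window to the endocortical chord of lateral sections so
    cortical bone is excluded, matching the 3D ROI convention.
    """
    per_section: dict[str, dict[str, float]] = {}
    for sec in sections:
        rect = (per_level_rects or {}).get(sec.level, site_rect)
        z = sec.axis_coords(0)
        y = sec.axis_coords(1)
        zc, yc = rect.center
        hz, hy = rect.extents[0] / 2.0, rect.extents[1] / 2.0
        zi = np.flatnonzero((z >= zc - hz) & (z <= zc + hz))
        yi = np.flatnonzero((y >= yc - hy) & (y <= yc + hy))
        if zi.size == 0 or yi.size == 0:
            raise ValueError("rect lies outside the section")
        window = sec.image[zi[0] : zi[-1] + 1, yi[0] : yi[-1] + 1]
        per_section[sec.level] = histo_intercepts(window, sec.pixel_size)
    mean = {k: float(np.mean([v[k] for v in per_section.values()]))
            for k in ("BVTV", "TbN", "TbTh", "TbSp")}
    return HistoResult(bvtv=mean["BVTV"], tbn=mean["TbN"], tbsp=mean["TbSp"],
                       tbth=mean["TbTh"], per_section=per_section)


def dxa_scan(volume: VoxelVolume, rect: Rect2D, projection_axis: int = 2) -> DxaResult:
    """Areal BMD (g/cm^2) of a sagittal-projection rectangle.

    Each (z, y) ray sums density x path length along the mediolateral axis;
    the areal BMD is the mean of this line integral over the rectangle.
    """
    if volume.units != "mg_per_cm3":
        raise ValueError("DXA projection needs a calibrated density volume")
    if projection_axis != 2:
        raise ValueError("only mediolateral (x) projection is supported")
    dx_cm = volume.spacing / 10.0
    areal = volume.values.sum(axis=2, dtype=np.float64) * dx_cm / 1000.0  # g/cm^2
    z = volume.axis_coords(0)
    y = volume.axis_coords(1)
    zc, yc = rect.center
    hz, hy = rect.extents[0] / 2.0, rect.extents[1] / 2.0
    zi = (z >= zc - hz) & (z <= zc + hz)
    yi = (y >= yc - hy) & (y <= yc + hy)
    if not zi.any() or not yi.any():
        raise ValueError("rect lies outside the projected extent")
    window = areal[np.ix_(zi, yi)]
    return DxaResult(areal_bmd=float(window.mean(dtype=np.float64)), rect=rect,
                     projection_axis=projection_axis)
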