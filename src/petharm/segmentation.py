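"""Sphere VOI delineation and background ROI placement.

Three region families feed the image-quality metrics:

* sphere VOIs — 3D isocontour at 50% of the maximum voxel value inside a
  search region around each nominal sphere position,
* the background battery — six concentric circular ROIs (diameters equal
  to the sphere diameters) replicated at 12 in-plane positions on 5 axial
  slices: 360 ROIs, 60 per size,
* the peak ROI — a floating 1-cm^3 sphere placed where its mean is
  highest, allowed to extend outside the delineated sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import BatteryPlacementError, SegmentationError
from .image import PetImage
from .phantom import PhantomSpec, SphereSpec

__all__ = [
    "SphereMask",
    "Roi",
    "RegionBattery",
    "PeakRoi",
    "segment_sphere",
    "segment_all_spheres",
    "place_background_battery",
    "find_peak_roi",
    "PEAK_ROI_VOLUME_MM3",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: Volume of the floating peak ROI (1 cm^3) and the resulting radius.
PEAK_ROI_VOLUME_MM3 = 1000.0
PEAK_ROI_RADIUS_MM = (3.0 * PEAK_ROI_VOLUME_MM3 / (4.0 * math.pi)) ** (1.0 / 3.0)

#: Segmentation-failure thresholds: a mask larger than 8x the nominal
#: sphere volume, or filling more than 90% of the search region, means the
#: 50% level set has merged with the background.
MAX_VOLUME_RATIO = 8.0
MAX_REGION_FILL = 0.90


@dataclass
class SphereMask:
    """A delineated sphere VOI on an image grid."""

    sphere: SphereSpec
    mask: np.ndarray  # boolean, same shape as the image
    max_voxel_value: float
    max_voxel_index: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_mm3(self, img: PetImage) -> float:
        return self.n_voxels * img.voxel_volume_mm3

    def indices(self) -> np.ndarray:
        return np.argwhere(self.mask)


def _search_radius_mm(sphere: SphereSpec) -> float:
    # generous enough that a merged mask is detectable for small spheres,
    # tight enough not to reach the neighbouring spheres for large ones
    return max(0.75 * sphere.inner_diameter_mm, sphere.radius_mm + 10.0)


def segment_sphere(
    img: PetImage, sphere: SphereSpec, search_radius_mm: float | None = None
) -> SphereMask:
    """Delineate one sphere with a 3D isocontour at 50% of its maximum.

    The threshold is half the maximum voxel value within a spherical
    search region around the nominal centre; the mask is the 26-connected
    component of supra-threshold voxels containing that maximum,
    intersected with the search region.  Raises
    :class:`~petharm.errors.SegmentationError` when the level set merges
    with the background (low contrast), mirroring the behaviour of
    isocontour tools on low-ratio fills.
    """
    if search_radius_mm is None:
        search_radius_mm = _search_radius_mm(sphere)
    xs, ys, zs = img.coordinate_grids()
    c = sphere.centre_mm
    region = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2 <= search_radius_mm**2
    if not region.any():
        raise SegmentationError("search region is outside the image grid")

    vals = np.where(region, img.voxels, -np.inf)
    max_idx = np.unravel_index(int(np.argmax(vals)), img.voxels.shape)
    vmax = float(img.voxels[max_idx])
    if vmax <= 0:
        raise SegmentationError(
            f"no positive signal near the {sphere.inner_diameter_mm:g}-mm sphere"
        )
    threshold = 0.5 * vmax

    above = (img.voxels >= threshold) & region
    labels, _ = ndimage.label(above, structure=_CONN26)
    comp = labels == labels[max_idx]

    nominal_vox = sphere.volume_mm3 / img.voxel_volume_mm3
    n = int(comp.sum())
    if n > MAX_VOLUME_RATIO * nominal_vox or n > MAX_REGION_FILL * int(region.sum()):
        raise SegmentationError(
            f"50% isocontour of the {sphere.inner_diameter_mm:g}-mm sphere merges "
            f"with the background ({n} voxels vs {nominal_vox:.0f} nominal)"
        )
    return SphereMask(sphere, comp, vmax, tuple(int(i) for i in max_idx))


def segment_all_spheres(img: PetImage, spec: PhantomSpec) -> dict[float, SphereMask]:
    """Segment every sphere of the phantom; keys are nominal diameters (mm)."""
    return {s.inner_diameter_mm: segment_sphere(img, s) for s in spec.spheres}


# ---------------------------------------------------------------------------
# background battery
# ---------------------------------------------------------------------------

@dataclass
class Roi:
    """One circular background ROI on one slice."""

    diameter_mm: float
    slice_index: int
    centre_mm: tuple[float, float]
    values: np.ndarray  # voxel values C_{i,r}

    @property
    def mean(self) -> float:  # C_{r,k}
        return float(np.mean(self.values))

    @property
    def n_voxels(self) -> int:  # I
        return int(self.values.size)


@dataclass
class RegionBattery:
    """The replicated background ROIs, grouped by nominal diameter."""

    rois: dict[float, list[Roi]] = field(default_factory=dict)

    def sizes(self) -> list[float]:
        return sorted(self.rois, reverse=True)

    def roi_means(self, diameter_mm: float) -> np.ndarray:
        return np.array([r.mean for r in self.rois[diameter_mm]])

    def grand_mean(self, diameter_mm: float) -> float:  # C-bar_r
        return float(self.roi_means(diameter_mm).mean())

    @property
    def total_rois(self) -> int:
        return sum(len(v) for v in self.rois.values())


# battery layout constants (mm / degrees); the replication counts are fixed
# by the analysis protocol, the geometric layout is this package's choice
BATTERY_RING_RADIUS_MM = 95.0
BATTERY_N_ANGLES = 12
BATTERY_ANGLE_OFFSET_DEG = 15.0
BATTERY_SLICE_OFFSETS_MM = (-20.0, -10.0, 0.0, 10.0, 20.0)
_RING_FALLBACKS_MM = (0.0, 10.0, -10.0)
_BODY_MARGIN_MM = 2.0


def _circle_inside_body(spec: PhantomSpec, cx: float, cy: float, r: float) -> bool:
    a, b = spec.body_half_axes_mm
    th = np.linspace(0, 2 * np.pi, 36, endpoint=False)
    px = cx + r * np.cos(th)
    py = cy + r * np.sin(th)
    return bool(np.all((px / (a - _BODY_MARGIN_MM)) ** 2 + (py / (b - _BODY_MARGIN_MM)) ** 2 <= 1.0))


def _circle_clear_of_lung(spec: PhantomSpec, cx: float, cy: float, r: float) -> bool:
    return math.hypot(cx, cy) >= spec.lung_radius_mm + r + _BODY_MARGIN_MM


def place_background_battery(
    img: PetImage,
    spec: PhantomSpec,
    masks: dict[float, SphereMask] | list[SphereMask],
) -> RegionBattery:
    """Place the 360-ROI background battery (12 positions x 5 slices x 6 sizes).

    The six concentric circles per position sit on a ring in the
    background, angularly offset from the sphere positions; the five
    slices are the central slice and +-10 / +-20 mm.  Placement is fully
    deterministic: a position whose largest circle would intersect a
    sphere mask, the lung insert or the body outline is shifted radially
    by +-10 mm; if no shift is admissible a
    :class:`~petharm.errors.BatteryPlacementError` is raised.
    """
    if isinstance(masks, dict):
        mask_list = list(masks.values())
    else:
        mask_list = list(masks)
    diameters = sorted((s.inner_diameter_mm for s in spec.spheres), reverse=True)
    r_max = 0.5 * diameters[0]

    zc = img.axis_coords(2)
    slice_indices = []
    for off in BATTERY_SLICE_OFFSETS_MM:
        iz = int(np.argmin(np.abs(zc - off)))
        if abs(zc[iz]) > 0.5 * spec.body_length_mm:
            raise BatteryPlacementError(f"battery slice at {off} mm is outside the body")
        slice_indices.append(iz)
    if len(set(slice_indices)) != len(slice_indices):
        raise BatteryPlacementError("voxel grid too coarse to separate battery slices")

    # sphere footprints on the battery slices (union over slices)
    footprint = np.zeros(img.voxels.shape[:2], dtype=bool)
    for m in mask_list:
        for iz in slice_indices:
            footprint |= m.mask[:, :, iz]

    xc = img.axis_coords(0)
    yc = img.axis_coords(1)
    xg = xc[:, None]
    yg = yc[None, :]

    def collides(cx: float, cy: float) -> bool:
        if not _circle_inside_body(spec, cx, cy, r_max):
            return True
        if not _circle_clear_of_lung(spec, cx, cy, r_max):
            return True
        disc = (xg - cx) ** 2 + (yg - cy) ** 2 <= r_max**2
        return bool((disc & footprint).any())

    centres = []
    for k in range(BATTERY_N_ANGLES):
        theta = math.radians(BATTERY_ANGLE_OFFSET_DEG + k * 360.0 / BATTERY_N_ANGLES)
        placed = False
        for dr in _RING_FALLBACKS_MM:
            rr = BATTERY_RING_RADIUS_MM + dr
            cx, cy = rr * math.cos(theta), rr * math.sin(theta)
            if not collides(cx, cy):
                centres.append((cx, cy))
                placed = True
                break
        if not placed:
            raise BatteryPlacementError(
                f"no admissible battery position at angle {math.degrees(theta):.0f} deg"
            )

    battery = RegionBattery({d: [] for d in diameters})
    for d in diameters:
        r = 0.5 * d
        for cx, cy in centres:
            disc = (xg - cx) ** 2 + (yg - cy) ** 2 <= r**2
            ii, jj = np.nonzero(disc)
            for iz in slice_indices:
                battery.rois[d].append(
                    Roi(d, iz, (cx, cy), img.voxels[ii, jj, iz].copy())
                )
    return battery


# ---------------------------------------------------------------------------
# peak ROI
# ---------------------------------------------------------------------------

@dataclass
class PeakRoi:
    """The floating 1-cm^3 spherical ROI at the hottest location."""

    centre_mm: tuple[float, float, float]
    radius_mm: float
    mean: float


def _peak_kernel(spacing: np.ndarray, supersample: int = 3) -> np.ndarray:
    """Fractional-occupancy weights of the 1-cm^3 sphere on the voxel grid."""
    half = np.ceil(PEAK_ROI_RADIUS_MM / spacing + 0.5).astype(int)
    ax = [spacing[d] * np.arange(-half[d], half[d] + 1) for d in range(3)]
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5
    w = np.zeros([len(a) for a in ax])
    for dx in sub:
        for dy in sub:
            for dz in sub:
                px = (ax[0] + dx * spacing[0])[:, None, None]
                py = (ax[1] + dy * spacing[1])[None, :, None]
                pz = (ax[2] + dz * spacing[2])[None, None, :]
                w += (px**2 + py**2 + pz**2) <= PEAK_ROI_RADIUS_MM**2
    return w / supersample**3


def find_peak_roi(img: PetImage, mask: SphereMask) -> PeakRoi:
    """Place the 1-cm^3 sphere where its (occupancy-weighted) mean is highest.

    Candidate centres are the voxel centres of the mask dilated by one
    voxel (the ROI itself may extend further); ties are broken by the
    lowest (z, y, x) index.
    """
    if mask.n_voxels == 0:
        raise SegmentationError("empty sphere mask")
    kernel = _peak_kernel(img.spacing)
    kernel = kernel / kernel.sum()

    cand = ndimage.binary_dilation(mask.mask, structure=_CONN26)
    idx = np.argwhere(cand)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    pad = np.array(kernel.shape) // 2
    lo_p = np.maximum(lo - pad, 0)
    hi_p = np.minimum(hi + pad, np.array(img.voxels.shape) - 1)
    sub = img.voxels[lo_p[0] : hi_p[0] + 1, lo_p[1] : hi_p[1] + 1, lo_p[2] : hi_p[2] + 1]
    means = ndimage.correlate(sub, kernel, mode="constant", cval=0.0)

    cand_sub = cand[lo_p[0] : hi_p[0] + 1, lo_p[1] : hi_p[1] + 1, lo_p[2] : hi_p[2] + 1]
    cand_means = np.where(cand_sub, means, -np.inf)
    best = cand_means.max()
    ties = np.argwhere(cand_means == best) + lo_p
    # exact ties (e.g. a single hot voxel surrounded by zeros): prefer the
    # candidate nearest the hottest voxel, then the lowest (z, y, x) index
    d2 = np.sum((ties - np.asarray(mask.max_voxel_index)) ** 2, axis=1)
    order = np.lexsort((ties[:, 0], ties[:, 1], ties[:, 2], d2))
    centre_idx = tuple(int(i) for i in ties[order[0]])
    centre = tuple(float(v) for v in img.index_to_world(centre_idx))
    return PeakRoi(centre, PEAK_ROI_RADIUS_MM, float(best))
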