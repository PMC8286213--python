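"""Edge-artifact quantification from 1D profiles and surface data.

For each delineated sphere the axial slice with the largest in-plane mask
area is selected; six profiles through the footprint centroid (30 deg
apart) are sampled by bilinear interpolation; the peak-to-valley ratio
(PTV) is the highest value along the whole profile divided by the lowest
value in the central part of the in-region samples.  The valley is
restricted to the central portion of the footprint because the artifact's
valley forms at the region centre, while the footprint edge always dips
toward half-maximum regardless of any artifact; with that rule an
artifact-free flat-top profile scores PTV = 1 and an overshoot ring
scores PTV > 1.

Spheres whose surface is a partial-volume dome ("conical") rather than a
rim-and-valley ("concave") get a not-measurable flag instead of a PTV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ProfilesUnavailableError, UndefinedPtvError
from .image import PetImage
from .segmentation import SphereMask

__all__ = [
    "Profile",
    "PtvResult",
    "largest_slice",
    "extract_profiles",
    "peak_to_valley",
    "classify_shape",
    "mean_ptv",
    "surface_data",
]

#: Valley search domain: central fraction of the in-region span after
#: excluding this fraction from each end (the artifact valley forms at
#: the region centre; the footprint edge always dips toward half-max).
VALLEY_EDGE_EXCLUSION = 0.3
#: Shape-classification constants (the module's reading of by-eye classes).
FLAT_RATIO_TOL = 1.02
CONCAVE_EDGE_FRACTION = 0.2
CONICAL_CENTRAL_FRACTION = 0.30

SHAPE_CLASSES = ("concave", "conical", "flat", "undefined")


@dataclass
class Profile:
    """A 1D interpolated profile through a sphere footprint.

    positions are mm along the line (0 at the footprint centroid),
    strictly increasing; in_region flags samples whose containing voxel
    belongs to the segmented footprint.
    """

    positions: np.ndarray
    values: np.ndarray
    in_region: np.ndarray
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if np.count_nonzero(self.in_region) < 5:
            raise ProfilesUnavailableError("fewer than 5 in-region samples")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    # -- derived geometry -------------------------------------------------
    def region_span(self) -> tuple[float, float]:
        p = self.positions[self.in_region]
        return float(p[0]), float(p[-1])

    def valley_selector(self, edge_fraction: float | None = None) -> np.ndarray:
        """Boolean selector of the central in-region samples (valley domain)."""
        if edge_fraction is None:
            edge_fraction = VALLEY_EDGE_EXCLUSION
        p0, p1 = self.region_span()
        margin = edge_fraction * (p1 - p0)
        sel = self.in_region & (self.positions >= p0 + margin) & (self.positions <= p1 - margin)
        if np.count_nonzero(sel) < 3:  # degenerate footprint: use whole region
            sel = self.in_region
        return sel

    def normalised_argmax(self) -> float:
        """Position of the in-region maximum on the [0, 1] footprint span."""
        p0, p1 = self.region_span()
        pin = self.positions[self.in_region]
        vin = self.values[self.in_region]
        return float((pin[np.argmax(vin)] - p0) / (p1 - p0)) if p1 > p0 else 0.5


@dataclass
class PtvResult:
    per_profile: list[float]
    mean: float
    sd: float
    shape: str
    measurable: bool


def largest_slice(mask: SphereMask) -> int:
    """Axial slice with the largest in-plane mask area (ties: nearest centroid)."""
    areas = mask.mask.sum(axis=(0, 1))
    best = areas.max()
    if best == 0:
        raise ProfilesUnavailableError("empty mask")
    candidates = np.nonzero(areas == best)[0]
    zc = float(np.argwhere(mask.mask)[:, 2].mean())
    return int(candidates[np.argmin(np.abs(candidates - zc))])


def extract_profiles(
    img: PetImage,
    mask: SphereMask,
    n_profiles: int = 6,
    step_mm: float = 0.5,
) -> list[Profile]:
    """Sample ``n_profiles`` lines through the footprint centroid.

    Lines are at angles k * (180 / n) degrees on the largest-area axial
    slice, sampled at ``step_mm`` by bilinear interpolation, and extend
    one footprint diameter beyond the footprint on each side.
    """
    iz = largest_slice(mask)
    foot = mask.mask[:, :, iz]
    idx = np.argwhere(foot)
    extent_vox = idx.max(axis=0) - idx.min(axis=0) + 1
    if min(extent_vox) < 2:
        raise ProfilesUnavailableError(
            "footprint narrower than 2 voxels; spatial resolution too limited"
        )
    # centroid and equivalent diameter of the footprint, in world mm
    centroid_idx = idx.mean(axis=0)
    cx = img.origin[0] + img.spacing[0] * centroid_idx[0]
    cy = img.origin[1] + img.spacing[1] * centroid_idx[1]
    area_mm2 = idx.shape[0] * img.spacing[0] * img.spacing[1]
    diameter = 2.0 * math.sqrt(area_mm2 / math.pi)

    half_len = 1.5 * diameter  # footprint radius + one diameter beyond
    t = np.arange(-half_len, half_len + 0.5 * step_mm, step_mm)

    plane = img.voxels[:, :, iz]
    profiles = []
    for k in range(n_profiles):
        ang = k * 180.0 / n_profiles
        ux, uy = math.cos(math.radians(ang)), math.sin(math.radians(ang))
        px = cx + t * ux
        py = cy + t * uy
        fx = (px - img.origin[0]) / img.spacing[0]
        fy = (py - img.origin[1]) / img.spacing[1]
        vals = ndimage.map_coordinates(plane, np.vstack([fx, fy]), order=1, mode="nearest")
        ix = np.clip(np.rint(fx).astype(int), 0, foot.shape[0] - 1)
        iy = np.clip(np.rint(fy).astype(int), 0, foot.shape[1] - 1)
        in_region = foot[ix, iy]
        profiles.append(Profile(t.copy(), vals, in_region, angle_deg=ang))
    return profiles


def peak_to_valley(profile: Profile) -> float:
    """PTV = max over the whole profile / min over the valley domain."""
    valley = float(profile.values[profile.valley_selector()].min())
    if valley <= 0:
        raise UndefinedPtvError("non-positive valley value")
    peak = float(profile.values.max())
    return peak / valley


def classify_shape(profiles: list[Profile]) -> str:
    """Classify the sphere surface: concave, conical, flat or undefined.

    flat    — in-region max over central min below the flatness tolerance,
    concave — majority of profiles peak within 20% of the footprint edge
              (overshoot rim with an interior valley),
    conical — majority peak in the central 30% (partial-volume dome).
    """
    ratios = []
    pos_max = []
    for p in profiles:
        vmax_in = float(p.values[p.in_region].max())
        vmin_c = float(p.values[p.valley_selector()].min())
        ratios.append(vmax_in / vmin_c if vmin_c > 0 else np.inf)
        pos_max.append(p.normalised_argmax())
    ratios = np.array(ratios)
    pos_max = np.array(pos_max)
    n = len(profiles)

    if np.median(ratios) < FLAT_RATIO_TOL:
        return "flat"
    near_edge = (pos_max <= CONCAVE_EDGE_FRACTION) | (pos_max >= 1.0 - CONCAVE_EDGE_FRACTION)
    if near_edge.sum() > n / 2:
        return "concave"
    half_c = 0.5 * CONICAL_CENTRAL_FRACTION
    central = np.abs(pos_max - 0.5) <= half_c
    if central.sum() > n / 2:
        return "conical"
    return "undefined"


def mean_ptv(profiles: list[Profile]) -> PtvResult:
    """Average PTV over the profiles; numeric only for concave/flat shapes."""
    shape = classify_shape(profiles)
    if shape not in ("concave", "flat"):
        return PtvResult([], float("nan"), float("nan"), shape, measurable=False)
    ptvs = [peak_to_valley(p) for p in profiles]
    arr = np.array(ptvs)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return PtvResult(ptvs, float(arr.mean()), sd, shape, measurable=True)


def surface_data(img: PetImage, mask: SphereMask, slice_index: int | None = None) -> np.ndarray:
    """In-plane value grid over the footprint bounding box + 1-voxel margin."""
    if slice_index is None:
        slice_index = largest_slice(mask)
    foot = mask.mask[:, :, slice_index]
    idx = np.argwhere(foot)
    if idx.size == 0:
        raise ProfilesUnavailableError("mask has no footprint on the requested slice")
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 1, np.array(foot.shape) - 1)
    return img.voxels[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, slice_index].copy()
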