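"""Quantitative image-quality metrics: RC, CRC, BV and IR.

Recovery coefficient            RC  = C_m / C_dc
Contrast recovery coefficient   CRC = (C_m - C_bkg,m) / (C_dc - C_bkg,dc)
Background variability          BV_r = sample SD of the K ROI means / grand mean
Image roughness                 IR_{r,k} = within-ROI voxel sample SD / ROI mean

C_dc and C_bkg,dc are the true (decay/residual-corrected) concentrations;
C_m is measured on the image: the hottest voxel (max), the VOI mean
(mean), or the 1-cm^3 peak ROI mean (peak).  BV and IR use sample
(K-1 / I-1) denominators.  IR is reported as the mean of the per-ROI
values over the 60 ROIs of a size (SD retained for diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidReferenceError
from .image import PetImage
from .phantom import FillSpec
from .segmentation import PeakRoi, RegionBattery, SphereMask

__all__ = [
    "recovery_coefficient",
    "contrast_recovery_coefficient",
    "background_variability",
    "image_roughness",
    "image_roughness_per_roi",
    "IQResult",
    "measure_iq",
]

RC_METRICS = ("RC_max", "RC_mean", "RC_peak")
CRC_METRICS = ("CRC_max", "CRC_mean", "CRC_peak")


def recovery_coefficient(c_m: float, c_dc: float) -> float:
    """RC = measured / true activity concentration."""
    if c_dc <= 0:
        raise InvalidReferenceError("true concentration C_dc must be > 0")
    return c_m / c_dc


def contrast_recovery_coefficient(
    c_m: float, c_bkg_m: float, c_dc: float, c_bkg_dc: float
) -> float:
    """CRC = measured contrast / true contrast."""
    if c_dc == c_bkg_dc:
        raise InvalidReferenceError("true contrast C_dc - C_bkg,dc must be non-zero")
    return (c_m - c_bkg_m) / (c_dc - c_bkg_dc)


def background_variability(battery: RegionBattery, diameter_mm: float) -> float:
    """Coefficient of variation of the K ROI means of one size."""
    means = battery.roi_means(diameter_mm)
    if means.size < 2:
        raise InsufficientDataError("background variability needs K >= 2 ROIs")
    grand = means.mean()
    if grand <= 0:
        raise InvalidReferenceError("non-positive background grand mean")
    return float(means.std(ddof=1) / grand)


def image_roughness_per_roi(battery: RegionBattery, diameter_mm: float) -> np.ndarray:
    """IR_{r,k} for every ROI of one size."""
    out = []
    for roi in battery.rois[diameter_mm]:
        if roi.n_voxels < 2:
            raise InsufficientDataError("image roughness needs I >= 2 voxels per ROI")
        m = roi.mean
        if m <= 0:
            raise InvalidReferenceError("non-positive ROI mean")
        out.append(float(np.std(roi.values, ddof=1) / m))
    return np.array(out)


def image_roughness(battery: RegionBattery, diameter_mm: float) -> float:
    """Mean IR over the ROIs of one size."""
    return float(image_roughness_per_roi(battery, diameter_mm).mean())


@dataclass
class IQResult:
    """All image-quality metrics of one acquisition/reconstruction.

    spheres : {diameter_mm: {RC_max, RC_mean, RC_peak, CRC_max, CRC_mean,
              CRC_peak}}
    noise   : {diameter_mm: {BV, IR, IR_sd}}
    labels  : free-form metadata (isotope, recon label, scanner, seed, ...)
    """

    spheres: dict[float, dict[str, float]]
    noise: dict[float, dict[str, float]]
    labels: dict = field(default_factory=dict)

    def diameters(self) -> list[float]:
        return sorted(self.spheres, reverse=True)

    def metric(self, name: str) -> dict[float, float]:
        """One metric for every sphere, keyed by diameter."""
        if name in ("BV", "IR", "IR_sd"):
            return {d: self.noise[d][name] for d in sorted(self.noise, reverse=True)}
        return {d: self.spheres[d][name] for d in self.diameters()}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for d in self.diameters():
            row = {"diameter_mm": d, **self.spheres[d]}
            if d in self.noise:
                row.update(self.noise[d])
            row.update(self.labels)
            rows.append(row)
        return pd.DataFrame(rows)


def measure_iq(
    img: PetImage,
    masks: dict[float, SphereMask],
    battery: RegionBattery,
    fill: FillSpec,
    peak_rois: dict[float, PeakRoi] | None = None,
    labels: dict | None = None,
) -> IQResult:
    """Assemble RC/CRC for every sphere and BV/IR for every ROI size.

    The measured background C_bkg,m for the CRC is the grand mean over the
    ROIs of the largest battery size (the most stable estimate); true
    concentrations are the fill values decay-corrected to scan time.
    """
    c_dc, c_bkg_dc = fill.concentrations_at_scan()
    largest = max(battery.rois)
    c_bkg_m = battery.grand_mean(largest)

    spheres: dict[float, dict[str, float]] = {}
    for d, mask in masks.items():
        vals = img.voxels[mask.mask]
        meas = {"max": float(vals.max()), "mean": float(vals.mean())}
        if peak_rois is not None and d in peak_rois:
            meas["peak"] = peak_rois[d].mean
        entry: dict[str, float] = {}
        for flavour, c_m in meas.items():
            entry[f"RC_{flavour}"] = recovery_coefficient(c_m, c_dc)
            entry[f"CRC_{flavour}"] = contrast_recovery_coefficient(
                c_m, c_bkg_m, c_dc, c_bkg_dc
            )
        spheres[d] = entry

    noise: dict[float, dict[str, float]] = {}
    for d in battery.sizes():
        per_roi = image_roughness_per_roi(battery, d)
        noise[d] = {
            "BV": background_variability(battery, d),
            "IR": float(per_roi.mean()),
            "IR_sd": float(per_roi.std(ddof=1)) if per_roi.size > 1 else 0.0,
        }

    return IQResult(spheres, noise, labels=dict(labels or {}))
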