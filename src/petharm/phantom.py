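"""NEMA IEC body-phantom description: geometry, fills, isotopes, reconstructions.

The NEMA IEC (image quality) phantom is a torso-shaped shell containing six
fillable spheres of 37, 28, 22, 17, 13 and 10 mm inner diameter, a central
cylindrical low-density "lung" insert, and a fillable background
compartment.  Everything downstream (simulation, segmentation, metrics)
consumes the dataclasses defined here.  Units are fixed to millimetres and
kBq/ml throughout the package; the phantom frame has its origin at the
phantom centre with axial slices perpendicular to the z axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import InvalidIsotopeError, UndefinedRatioError

__all__ = [
    "SphereSpec",
    "PhantomSpec",
    "FillSpec",
    "IsotopeSpec",
    "ReconConfig",
    "GA68",
    "F18",
    "NEMA_SPHERE_DIAMETERS_MM",
    "default_nema_spec",
    "decay_correct",
    "fill_ratio",
]

#: Inner diameters (mm) of the six NEMA IQ spheres, largest first.
NEMA_SPHERE_DIAMETERS_MM: tuple[float, ...] = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)

#: Diameter (mm) of the ring on which the sphere centres sit (standard IEC layout).
SPHERE_RING_DIAMETER_MM = 114.4


@dataclass(frozen=True)
class IsotopeSpec:
    """A positron emitter: name, physical half-life and mean positron range.

    The mean positron range in water controls the isotope-dependent
    resolution loss in the simulator; Ga-68 positrons travel roughly five
    times further than F-18 positrons before annihilating.
    """

    name: str
    half_life_min: float
    mean_positron_range_mm: float

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise InvalidIsotopeError(
                f"half-life must be positive, got {self.half_life_min}"
            )
        if self.mean_positron_range_mm < 0:
            raise InvalidIsotopeError("mean positron range must be >= 0")


GA68 = IsotopeSpec("Ga-68", half_life_min=68.0, mean_positron_range_mm=2.9)
F18 = IsotopeSpec("F-18", half_life_min=109.8, mean_positron_range_mm=0.6)


@dataclass(frozen=True)
class SphereSpec:
    """One hot sphere: inner diameter and centre in the phantom frame (mm)."""

    inner_diameter_mm: float
    centre_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.inner_diameter_mm <= 0:
            raise ValueError("sphere diameter must be positive")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.inner_diameter_mm

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_mm**3


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom geometry.

    body_half_axes_mm : (a, b) of the elliptical-cylinder torso outline
    body_length_mm    : axial extent of the body compartment
    lung_radius_mm / lung_length_mm : central cold cylinder (zero activity)
    """

    spheres: tuple[SphereSpec, ...]
    body_half_axes_mm: tuple[float, float] = (150.0, 115.0)
    body_length_mm: float = 180.0
    lung_radius_mm: float = 25.0
    lung_length_mm: float = 180.0

    def sphere_by_diameter(self, diameter_mm: float) -> SphereSpec:
        for s in self.spheres:
            if abs(s.inner_diameter_mm - diameter_mm) < 1e-9:
                return s
        raise KeyError(f"no sphere with diameter {diameter_mm} mm")

    def diameters(self) -> tuple[float, ...]:
        return tuple(s.inner_diameter_mm for s in self.spheres)

    def inside_body(self, x, y, z):
        """Vectorised membership test for the body compartment (incl. spheres/lung)."""
        a, b = self.body_half_axes_mm
        r2 = (np.asarray(x) / a) ** 2 + (np.asarray(y) / b) ** 2
        return (r2 <= 1.0) & (np.abs(np.asarray(z)) <= 0.5 * self.body_length_mm)

    def inside_lung(self, x, y, z):
        r2 = np.asarray(x) ** 2 + np.asarray(y) ** 2
        return (r2 <= self.lung_radius_mm**2) & (
            np.abs(np.asarray(z)) <= 0.5 * self.lung_length_mm
        )

    def to_dict(self) -> dict:
        return {
            "spheres": [
                {"diameter_mm": s.inner_diameter_mm, "centre_mm": list(s.centre_mm)}
                for s in self.spheres
            ],
            "body": {
                "half_axes_mm": list(self.body_half_axes_mm),
                "length_mm": self.body_length_mm,
            },
            "lung_insert": {
                "radius_mm": self.lung_radius_mm,
                "length_mm": self.lung_length_mm,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        spheres = tuple(
            SphereSpec(s["diameter_mm"], tuple(s["centre_mm"])) for s in d["spheres"]
        )
        body = d.get("body", {})
        lung = d.get("lung_insert", {})
        return cls(
            spheres=spheres,
            body_half_axes_mm=tuple(body.get("half_axes_mm", (150.0, 115.0))),
            body_length_mm=body.get("length_mm", 180.0),
            lung_radius_mm=lung.get("radius_mm", 25.0),
            lung_length_mm=lung.get("length_mm", 180.0),
        )


def default_nema_spec() -> PhantomSpec:
    """The six-sphere NEMA IQ phantom with the standard coplanar layout.

    Sphere centres sit in one axial plane (z = 0) on a 114.4-mm-diameter
    ring at 60 deg spacing, largest sphere at angle 0; the lung insert is
    centred on the phantom axis.  The list is sorted by descending diameter
    and identical across calls.
    """
    ring_r = 0.5 * SPHERE_RING_DIAMETER_MM
    spheres = []
    for k, d in enumerate(NEMA_SPHERE_DIAMETERS_MM):
        theta = math.radians(60.0 * k)
        centre = (ring_r * math.cos(theta), ring_r * math.sin(theta), 0.0)
        spheres.append(SphereSpec(d, centre))
    return PhantomSpec(spheres=tuple(spheres))


@dataclass(frozen=True)
class FillSpec:
    """Activity concentrations (kBq/ml) at fill time plus timing metadata.

    ``residual_factor`` is an optional multiplicative correction for
    activity left in the syringe/vial after filling (1.0 = no residual).
    Elapsed time from fill to scan is expressed in minutes.
    """

    sphere_concentration_kbq_ml: float
    background_concentration_kbq_ml: float
    isotope: IsotopeSpec = GA68
    fill_to_scan_min: float = 0.0
    residual_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.sphere_concentration_kbq_ml < 0 or self.background_concentration_kbq_ml < 0:
            raise ValueError("concentrations must be >= 0")
        if self.residual_factor <= 0:
            raise ValueError("residual factor must be positive")

    def concentrations_at_scan(self) -> tuple[float, float]:
        """Sphere and background concentration decay-corrected to scan time."""
        s = decay_correct(
            self.sphere_concentration_kbq_ml, self.fill_to_scan_min, self.isotope
        )
        b = decay_correct(
            self.background_concentration_kbq_ml, self.fill_to_scan_min, self.isotope
        )
        return s * self.residual_factor, b * self.residual_factor

    def to_dict(self) -> dict:
        return {
            "sphere_kbq_ml": self.sphere_concentration_kbq_ml,
            "background_kbq_ml": self.background_concentration_kbq_ml,
            "isotope": {
                "name": self.isotope.name,
                "half_life_min": self.isotope.half_life_min,
                "mean_positron_range_mm": self.isotope.mean_positron_range_mm,
            },
            "fill_to_scan_min": self.fill_to_scan_min,
            "residual_factor": self.residual_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FillSpec":
        iso = d.get("isotope", {})
        isotope = IsotopeSpec(
            iso.get("name", "Ga-68"),
            iso.get("half_life_min", 68.0),
            iso.get("mean_positron_range_mm", 2.9),
        )
        return cls(
            sphere_concentration_kbq_ml=d["sphere_kbq_ml"],
            background_concentration_kbq_ml=d["background_kbq_ml"],
            isotope=isotope,
            fill_to_scan_min=d.get("fill_to_scan_min", 0.0),
            residual_factor=d.get("residual_factor", 1.0),
        )


#: Default fill of the optimisation experiment: 19.9 / 2.4 kBq/ml (8.29:1).
DEFAULT_GA68_FILL = FillSpec(19.9, 2.4, isotope=GA68)


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction-variant label understood by the simulator.

    family       : "conventional" (OSEM/OSEM+TOF), "psf" or "bpl"
    gaussian_fwhm_mm : post-reconstruction Gaussian filter width w
                       (conventional/psf families)
    penalisation : unitless beta of the penalised-likelihood family (bpl only)
    """

    family: str
    gaussian_fwhm_mm: float = 0.0
    penalisation: float | None = None
    label: str | None = None

    FAMILIES = ("conventional", "psf", "bpl")

    def __post_init__(self) -> None:
        if self.family not in self.FAMILIES:
            raise ValueError(f"unknown reconstruction family {self.family!r}")
        if self.family == "bpl":
            if self.penalisation is None or self.penalisation < 0:
                raise ValueError("bpl requires a non-negative penalisation factor")
        elif self.gaussian_fwhm_mm < 0:
            raise ValueError("gaussian filter width must be >= 0")
        if self.label is None:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.family == "bpl":
            return f"BPL_{self.penalisation:g}"
        prefix = "PSF" if self.family == "psf" else "OSEM"
        return f"{prefix}_{self.gaussian_fwhm_mm:g}"

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "gaussian_fwhm_mm": self.gaussian_fwhm_mm,
            "penalisation": self.penalisation,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReconConfig":
        return cls(
            family=d["family"],
            gaussian_fwhm_mm=d.get("gaussian_fwhm_mm", 0.0),
            penalisation=d.get("penalisation"),
            label=d.get("label"),
        )


#: The post-filter widths and penalisation factors of the optimisation sweep.
DEFAULT_FILTER_WIDTHS_MM = (2.0, 4.0, 5.0, 6.4)
DEFAULT_PENALISATIONS = (200.0, 400.0, 600.0, 800.0, 1000.0, 1200.0)


def decay_correct(
    concentration_kbq_ml: float, elapsed_min: float, isotope: IsotopeSpec
) -> float:
    """Radioactive-decay correction: concentration x 2^(-elapsed / half-life).

    Negative ``elapsed_min`` back-corrects to an earlier time point.
    """
    if isotope.half_life_min <= 0:  # defensive: IsotopeSpec already validates
        raise InvalidIsotopeError("half-life must be positive")
    return concentration_kbq_ml * 2.0 ** (-elapsed_min / isotope.half_life_min)


def fill_ratio(fill: FillSpec) -> float:
    """Sphere-to-background concentration ratio (decay cancels, same isotope)."""
    if fill.background_concentration_kbq_ml <= 0:
        raise UndefinedRatioError("background concentration must be > 0")
    return fill.sphere_concentration_kbq_ml / fill.background_concentration_kbq_ml


def config_to_yaml(
    spec: PhantomSpec, fill: FillSpec, recon: ReconConfig | None = None
) -> str:
    """Serialise a phantom/fill/recon block to YAML (see io module for files)."""
    block: dict = spec.to_dict()
    block["fill"] = fill.to_dict()
    if recon is not None:
        block["recon"] = recon.to_dict()
    return yaml.safe_dump(block, sort_keys=False)


def config_from_yaml(text: str) -> tuple[PhantomSpec, FillSpec, ReconConfig | None]:
    d = yaml.safe_load(text)
    spec = PhantomSpec.from_dict(d)
    fill = FillSpec.from_dict(d["fill"])
    recon = ReconConfig.from_dict(d["recon"]) if "recon" in d else None
    return spec, fill, recon
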