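"""Synthetic PET acquisitions of the NEMA IQ phantom.

The simulator produces images whose resolution, edge-artifact and noise
behaviour reproduce the qualitative structure of reconstructed scanner
data, without any projection-domain physics:

* ``rasterize``        — voxelise the phantom with fractional sphere
                          occupancy (digital ground truth),
* ``resolution_blur``  — Gaussian blur combining scanner PSF and
                          isotope-dependent positron range,
* ``edge_enhance``     — difference-of-Gaussians sharpening emulating the
                          Gibbs-type overshoot of PSF/penalised-likelihood
                          reconstructions,
* ``add_noise``        — spatially correlated, locally scaled Gaussian
                          noise with a reproducible stream,
* ``post_filter``      — the post-reconstruction Gaussian filter,
* ``simulate_acquisition`` / ``simulate_ensemble`` — full chains and
                          multi-scanner ensembles with controlled
                          inter-scanner variation.

The per-stage emulation constants (positron-range factor, overshoot
kernel width, the alpha(beta) / smoothing(beta) maps of the penalised
family) are module-level and documented in docs/methods.md; they are
simulator knobs chosen to reproduce trend directions, not claims about
any vendor algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import GeometryClippedError, InvalidParameterError
from .image import PetImage
from .phantom import FillSpec, IsotopeSpec, PhantomSpec, ReconConfig

__all__ = [
    "ScannerProfile",
    "JitterSpec",
    "DEFAULT_SCANNER",
    "DEFAULT_VOXEL_PRESETS_MM",
    "rasterize",
    "resolution_blur",
    "edge_enhance",
    "add_noise",
    "post_filter",
    "simulate_acquisition",
    "simulate_ensemble",
    "calibrate_noise_level",
    "ground_truth_masks",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Gaussian-equivalent positron blur: FWHM = 2 x mean range x this factor.
#: The true annihilation-point distribution is cusp-shaped; only the
#: relative Ga-68 vs F-18 behaviour matters here.
POSITRON_FWHM_FACTOR = 0.85

#: Width (mm) of the wide Gaussian in the difference-of-Gaussians
#: sharpening kernel; sets the spatial scale of the edge overshoot ring.
#: Narrow enough that a 6.4-mm post filter largely suppresses the ring.
EDGE_DOG_FWHM_MM = 5.0

#: Penalised-likelihood emulation: overshoot amplitude alpha(beta) =
#: edge_strength * exp(-beta/BPL_BETA0) and effective internal smoothing
#: s(beta) = BPL_SMAX_MM * (1 - exp(-beta/BPL_BETA0)).  beta = 200 then
#: shows strong overshoot and noise, beta >= 800 suppresses both.
BPL_BETA0 = 400.0
BPL_SMAX_MM = 7.0

#: Voxel-size presets mirroring the range of clinical reconstruction
#: matrices across the participating scanner models (mm).
DEFAULT_VOXEL_PRESETS_MM = (
    (2.7, 2.7, 3.3),
    (4.1, 4.1, 2.0),
    (5.5, 5.5, 3.3),
)


@dataclass(frozen=True)
class ScannerProfile:
    """Per-scanner acquisition characteristics.

    edge_strength is the overshoot amplitude alpha before any smoothing:
    it applies directly for the psf family and is attenuated by
    exp(-beta/BPL_BETA0) for the bpl family.  noise_level is the target
    coefficient of variation of the injected background noise (before the
    post filter); 0 gives a noiseless acquisition.
    """

    name: str = "scanner"
    psf_fwhm_mm: float = 4.5
    voxel_spacing_mm: tuple[float, float, float] = (2.7, 2.7, 3.3)
    calibration_bias: float = 1.0
    edge_strength: float = 3.0
    noise_level: float = 0.0
    noise_correlation_fwhm_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm <= 0:
            raise InvalidParameterError("psf_fwhm_mm must be > 0")
        if self.calibration_bias <= 0:
            raise InvalidParameterError("calibration_bias must be > 0")
        if self.noise_level < 0 or self.edge_strength < 0:
            raise InvalidParameterError("noise_level and edge_strength must be >= 0")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "psf_fwhm_mm": self.psf_fwhm_mm,
            "voxel_spacing_mm": list(self.voxel_spacing_mm),
            "calibration_bias": self.calibration_bias,
            "edge_strength": self.edge_strength,
            "noise_level": self.noise_level,
            "noise_correlation_fwhm_mm": self.noise_correlation_fwhm_mm,
        }


DEFAULT_SCANNER = ScannerProfile()


def _sigma_voxels(fwhm_mm: float, spacing: np.ndarray) -> np.ndarray:
    return fwhm_mm * FWHM_TO_SIGMA / np.asarray(spacing, dtype=float)


def _gaussian(voxels: np.ndarray, fwhm_mm: float, spacing: np.ndarray) -> np.ndarray:
    if fwhm_mm <= 0:
        return voxels.copy()
    return ndimage.gaussian_filter(
        voxels, sigma=_sigma_voxels(fwhm_mm, spacing), mode="constant", cval=0.0
    )


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def default_grid(
    spec: PhantomSpec, spacing, margin_mm: float = 8.0
) -> tuple[tuple[int, int, int], np.ndarray]:
    """Shape and origin of a grid centred on the phantom that contains the body."""
    spacing = np.asarray(spacing, dtype=float)
    half_extent = np.array(
        [
            spec.body_half_axes_mm[0] + margin_mm,
            spec.body_half_axes_mm[1] + margin_mm,
            0.5 * spec.body_length_mm + margin_mm,
        ]
    )
    shape = np.ceil(2 * half_extent / spacing).astype(int)
    # voxel-centre origin so that the grid is symmetric about the phantom centre
    origin = -(shape - 1) / 2.0 * spacing
    return tuple(int(n) for n in shape), origin


def rasterize(
    spec: PhantomSpec,
    fill: FillSpec,
    spacing,
    shape: tuple[int, int, int] | None = None,
    origin=None,
    supersample: int = 3,
) -> PetImage:
    """Voxelise the phantom at scan-time concentrations.

    Each voxel gets ``background + (sphere - background) * f`` where f is
    the fraction of the voxel inside a sphere, estimated by
    ``supersample**3`` sub-voxel sampling; lung-insert voxels are 0 and
    voxels outside the body outline are 0.  Body and lung membership use a
    voxel-centre test (their edges carry no metric).
    """
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise InvalidParameterError("spacing must be positive")
    if shape is None or origin is None:
        shape, origin = default_grid(spec, spacing)
    origin = np.asarray(origin, dtype=float)
    shape = tuple(int(n) for n in shape)

    img = PetImage(np.zeros(shape), spacing, origin, meta={"stage": "rasterize"})
    xs, ys, zs = img.coordinate_grids()

    # grid must contain the body outline
    lo = origin - spacing / 2.0
    hi = origin + spacing * (np.array(shape) - 0.5)
    body_hi = np.array(
        [spec.body_half_axes_mm[0], spec.body_half_axes_mm[1], spec.body_length_mm / 2]
    )
    if np.any(lo > -body_hi) or np.any(hi < body_hi):
        raise GeometryClippedError(
            f"grid extent [{lo}, {hi}] does not contain the phantom body"
        )

    sphere_c, bkg_c = fill.concentrations_at_scan()

    body = spec.inside_body(xs, ys, zs)
    lung = spec.inside_lung(xs, ys, zs)
    vox = np.where(body & ~lung, bkg_c, 0.0)

    # fractional sphere occupancy inside each sphere's bounding box
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5  # in voxel units
    for s in spec.spheres:
        c = np.asarray(s.centre_mm)
        r = s.radius_mm
        lo_idx = np.floor((c - r - origin) / spacing - 0.5).astype(int)
        hi_idx = np.ceil((c + r - origin) / spacing + 0.5).astype(int)
        lo_idx = np.maximum(lo_idx, 0)
        hi_idx = np.minimum(hi_idx, np.array(shape) - 1)
        sl = tuple(slice(a, b + 1) for a, b in zip(lo_idx, hi_idx))
        # voxel-centre coordinates of the bounding box, relative to the sphere
        ax = [
            origin[d] + spacing[d] * np.arange(lo_idx[d], hi_idx[d] + 1) - c[d]
            for d in range(3)
        ]
        frac = np.zeros([len(a) for a in ax])
        for dx in sub:
            for dy in sub:
                for dz in sub:
                    px = (ax[0] + dx * spacing[0])[:, None, None]
                    py = (ax[1] + dy * spacing[1])[None, :, None]
                    pz = (ax[2] + dz * spacing[2])[None, None, :]
                    frac += (px**2 + py**2 + pz**2) <= r**2
        frac /= supersample**3
        vox[sl] += (sphere_c - bkg_c) * frac

    img.voxels = vox
    img.meta.update({"fill": fill.to_dict()})
    return img


def ground_truth_masks(spec: PhantomSpec, img: PetImage, mode: str = "interior"):
    """Voxel-index masks of the nominal spheres on an image grid.

    mode="interior": voxels entirely inside the nominal sphere (centre
    within radius minus half the voxel diagonal) — plateau voxels only,
    free of partial-volume edges.  mode="centre": plain centre-in test.
    Returned as {diameter_mm: boolean array}; used for simulator ground
    truth and chain-identity checks.
    """
    xs, ys, zs = img.coordinate_grids()
    half_diag = 0.5 * float(np.linalg.norm(img.spacing))
    out = {}
    for s in spec.spheres:
        c = s.centre_mm
        r = s.radius_mm - (half_diag if mode == "interior" else 0.0)
        if r <= 0:
            raise InvalidParameterError(
                f"voxel grid too coarse for an interior mask of the "
                f"{s.inner_diameter_mm:g}-mm sphere"
            )
        d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2
        out[s.inner_diameter_mm] = d2 <= r**2
    return out


# ---------------------------------------------------------------------------
# image-domain reconstruction emulation
# ---------------------------------------------------------------------------

def positron_fwhm_mm(isotope: IsotopeSpec, factor: float = POSITRON_FWHM_FACTOR) -> float:
    """Gaussian-equivalent FWHM of the positron-range blur for an isotope."""
    return 2.0 * isotope.mean_positron_range_mm * factor


def resolution_blur(
    img: PetImage, isotope: IsotopeSpec, psf_fwhm_mm: float
) -> PetImage:
    """Blur with effective FWHM = sqrt(psf^2 + positron^2) (quadrature)."""
    if psf_fwhm_mm < 0:
        raise InvalidParameterError("psf_fwhm_mm must be >= 0")
    eff = math.hypot(psf_fwhm_mm, positron_fwhm_mm(isotope))
    out = _gaussian(img.voxels, eff, img.spacing)
    return img.copy_with(out, stage="resolution_blur", effective_fwhm_mm=eff)


def edge_enhance(
    img: PetImage, strength: float, edge_fwhm_mm: float | None = None
) -> PetImage:
    """Difference-of-Gaussians sharpening producing overshoot at boundaries.

    out = (1 + alpha) * img - alpha * G_wide(img); alpha = 0 is the
    identity.  Negative values created by the sharpening are clipped to 0
    (concentration images are non-negative).
    """
    if edge_fwhm_mm is None:
        edge_fwhm_mm = EDGE_DOG_FWHM_MM
    if strength < 0:
        raise InvalidParameterError("edge strength must be >= 0")
    if strength == 0:
        return img.copy_with(img.voxels.copy(), stage="edge_enhance", alpha=0.0)
    wide = _gaussian(img.voxels, edge_fwhm_mm, img.spacing)
    out = np.clip((1.0 + strength) * img.voxels - strength * wide, 0.0, None)
    return img.copy_with(out, stage="edge_enhance", alpha=strength)


def add_noise(
    img: PetImage,
    noise_level: float,
    correlation_fwhm_mm: float,
    seed: int,
    reference_kbq_ml: float | None = None,
) -> PetImage:
    """Add spatially correlated, locally scaled Gaussian noise.

    The voxelwise standard deviation is
    ``noise_level * sqrt(local_mean * reference)`` — proportional noise
    with a Poisson-like square-root dependence on the local signal; in a
    uniform background at the reference level the injected coefficient of
    variation equals ``noise_level``.  The white field is smoothed by a
    Gaussian of ``correlation_fwhm_mm`` and renormalised to unit variance,
    so the correlation length can be varied without changing the marginal
    noise amplitude (decoupling background variability from image
    roughness).  Identical seed and inputs give identical output.
    """
    if noise_level < 0:
        raise InvalidParameterError("noise_level must be >= 0")
    if noise_level == 0:
        return img.copy_with(img.voxels.copy(), stage="add_noise", noise_level=0.0)
    if reference_kbq_ml is None:
        pos = img.voxels[img.voxels > 0]
        reference_kbq_ml = float(np.median(pos)) if pos.size else 1.0
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(img.voxels.shape)
    if correlation_fwhm_mm > 0:
        white = _gaussian(white, correlation_fwhm_mm, img.spacing)
        sd = float(white.std())
        if sd > 0:
            white /= sd
    sigma = noise_level * np.sqrt(np.clip(img.voxels, 0.0, None) * reference_kbq_ml)
    out = np.clip(img.voxels + sigma * white, 0.0, None)
    return img.copy_with(
        out,
        stage="add_noise",
        noise_level=noise_level,
        noise_correlation_fwhm_mm=correlation_fwhm_mm,
        noise_seed=int(seed),
    )


def post_filter(img: PetImage, fwhm_mm: float) -> PetImage:
    """Post-reconstruction Gaussian smoothing of width ``fwhm_mm`` (0 = identity)."""
    if fwhm_mm < 0:
        raise InvalidParameterError("filter width must be >= 0")
    out = _gaussian(img.voxels, fwhm_mm, img.spacing)
    return img.copy_with(out, stage="post_filter", post_filter_fwhm_mm=fwhm_mm)


def bpl_effective_params(beta: float, edge_strength: float) -> tuple[float, float]:
    """(alpha, smoothing FWHM mm) of the penalised-likelihood emulation."""
    alpha = edge_strength * math.exp(-beta / BPL_BETA0)
    smooth = BPL_SMAX_MM * (1.0 - math.exp(-beta / BPL_BETA0))
    return alpha, smooth


# fixed offsets for per-stage child seeds (stages re-runnable independently)
_NOISE_SEED_OFFSET = 101
_ENSEMBLE_SEED_OFFSET = 7919
_SEED_MOD = 2**31 - 1


def simulate_acquisition(
    spec: PhantomSpec,
    fill: FillSpec,
    scanner: ScannerProfile,
    recon: ReconConfig,
    seed: int = 0,
) -> PetImage:
    """Full acquisition chain for one scanner and reconstruction variant.

    rasterize -> resolution blur -> edge enhancement (psf/bpl families)
    -> noise -> post filter -> calibration bias.  Deterministic under a
    fixed seed; all parameters are recorded in the image meta.
    """
    img = rasterize(spec, fill, scanner.voxel_spacing_mm)
    img = resolution_blur(img, fill.isotope, scanner.psf_fwhm_mm)

    if recon.family == "bpl":
        alpha, smooth = bpl_effective_params(recon.penalisation, scanner.edge_strength)
    elif recon.family == "psf":
        alpha, smooth = scanner.edge_strength, recon.gaussian_fwhm_mm
    else:
        alpha, smooth = 0.0, recon.gaussian_fwhm_mm

    if alpha > 0:
        img = edge_enhance(img, alpha)
    if scanner.noise_level > 0:
        img = add_noise(
            img,
            scanner.noise_level,
            scanner.noise_correlation_fwhm_mm,
            seed=(seed + _NOISE_SEED_OFFSET) % _SEED_MOD,
        )
    img = post_filter(img, smooth)
    img.voxels = img.voxels * scanner.calibration_bias
    img.meta.update(
        {
            "scanner": scanner.to_dict(),
            "recon": recon.to_dict(),
            "seed": int(seed),
            "isotope": fill.isotope.name,
        }
    )
    return img


@dataclass(frozen=True)
class JitterSpec:
    """Inter-scanner variation of a simulated multi-centre ensemble.

    calibration_bias_sd : SD of the multiplicative calibration bias
                          (normal around the base profile's bias)
    psf_fwhm_sd_mm      : SD of the scanner resolution
    noise_level_sd      : SD of the injected noise level (clipped at 0)
    vary_voxels         : cycle scanners through ``voxel_presets_mm``
    """

    calibration_bias_sd: float = 0.03
    psf_fwhm_sd_mm: float = 0.0
    noise_level_sd: float = 0.0
    vary_voxels: bool = False
    voxel_presets_mm: tuple = DEFAULT_VOXEL_PRESETS_MM


def simulate_ensemble(
    spec: PhantomSpec,
    fill: FillSpec,
    recon: ReconConfig,
    n_scanners: int,
    base_profile: ScannerProfile = DEFAULT_SCANNER,
    jitter: JitterSpec = JitterSpec(),
    seed: int = 0,
) -> list[tuple[PetImage, ScannerProfile]]:
    """Simulate one multi-centre ensemble; returns (image, true profile) pairs.

    Per-scanner profiles are drawn around the base profile with the
    jitter-spec dispersions, so recovery of the generator's between-scanner
    variation can be tested against the returned ground-truth profiles.
    """
    if n_scanners < 2:
        raise InvalidParameterError("an ensemble needs at least 2 scanners")
    rng = np.random.default_rng((seed + _ENSEMBLE_SEED_OFFSET) % _SEED_MOD)
    out = []
    for i in range(n_scanners):
        bias = base_profile.calibration_bias * (
            1.0 + jitter.calibration_bias_sd * rng.standard_normal()
        )
        psf = max(0.5, base_profile.psf_fwhm_mm + jitter.psf_fwhm_sd_mm * rng.standard_normal())
        noise = max(0.0, base_profile.noise_level + jitter.noise_level_sd * rng.standard_normal())
        voxels = (
            jitter.voxel_presets_mm[i % len(jitter.voxel_presets_mm)]
            if jitter.vary_voxels
            else base_profile.voxel_spacing_mm
        )
        profile = replace(
            base_profile,
            name=f"{base_profile.name}_{i}",
            calibration_bias=max(bias, 1e-6),
            psf_fwhm_mm=psf,
            noise_level=noise,
            voxel_spacing_mm=tuple(voxels),
        )
        img = simulate_acquisition(spec, fill, profile, recon, seed=seed * 1009 + i)
        out.append((img, profile))
    return out


def calibrate_noise_level(
    run, target: float, initial: float = 0.3, n_iter: int = 3
) -> float:
    """Closed-loop calibration of ``noise_level`` against a measured noise metric.

    ``run(noise_level)`` must return the measured metric (e.g. background
    image roughness).  The injected amplitude is approximately proportional
    to the measured metric, so a few proportional updates converge.
    """
    level = initial
    for _ in range(n_iter):
        measured = run(level)
        if measured <= 0:
            level *= 2.0
            continue
        level *= target / measured
    return level
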