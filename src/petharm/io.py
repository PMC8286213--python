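"""Image I/O, run configuration and the experiment presets.

NIfTI-1 is the canonical on-disk image format (float32 voxels, mm
spacings, kBq/ml stated in the description field) with a JSON sidecar
carrying fill/reconstruction/scanner metadata; DICOM series are
read-only.  ``run_experiment`` chains simulation, segmentation, metrics
and the downstream stages into the three phantom experiments plus the
clinical-agreement stage, writing CSV/JSON reports and a manifest that
makes every output traceable to a config digest and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
import yaml

from .clinical import bland_altman, generate_synthetic_lesions, lesion_pairs
from .errors import FormatError, InvalidParameterError, SegmentationError
from .harmonise import LimitsTable, aggregate, check_compliance, derive_limits
from .image import PetImage
from .metrics import IQResult, measure_iq
from .phantom import (
    DEFAULT_FILTER_WIDTHS_MM,
    DEFAULT_GA68_FILL,
    DEFAULT_PENALISATIONS,
    FillSpec,
    PhantomSpec,
    ReconConfig,
    default_nema_spec,
)
from .profiles import ProfilesUnavailableError, extract_profiles, mean_ptv
from .segmentation import (
    find_peak_roi,
    place_background_battery,
    segment_all_spheres,
)
from .simulate import JitterSpec, ScannerProfile, simulate_acquisition, simulate_ensemble

logger = logging.getLogger("petharm")

__all__ = [
    "read_image",
    "write_image",
    "RunConfig",
    "run_experiment",
    "analyse_acquisition",
]

EXPERIMENTS = ("optimise", "multicentre", "clinical", "contrast_sweep")


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def write_image(img: PetImage, path, sidecar: bool = True) -> Path:
    """Write a PetImage as NIfTI-1 (float32, voxel-centre origin in mm)."""
    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(img.spacing)
    affine[:3, 3] = img.origin
    nii = nib.Nifti1Image(np.asarray(img.voxels, dtype=np.float32), affine)
    nii.header.set_xyzt_units("mm")
    nii.header["descrip"] = b"activity concentration kBq/ml"
    nib.save(nii, path)
    if sidecar and img.meta:
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(img.meta, indent=2, sort_keys=True, default=str)
        )
    return path


def _read_nifti(path: Path) -> PetImage:
    nii = nib.load(path)
    affine = nii.affine
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-3 * max(1.0, np.max(np.abs(rot))):
        raise FormatError(f"{path}: oblique affines are not supported")
    data = np.asarray(nii.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got shape {data.shape}")
    scale = np.diag(rot)
    origin = affine[:3, 3].copy()
    for ax in range(3):
        if scale[ax] < 0:  # flip to keep positive spacing, voxel-centre origin
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] + scale[ax] * (data.shape[ax] - 1)
            scale[ax] = -scale[ax]
    return PetImage(data, scale, origin, meta={"source": str(path)})


def _read_dicom_series(path: Path) -> PetImage:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in ("", ".dcm", ".ima"))
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:  # non-DICOM file in the directory
            continue
        if hasattr(ds, "ImagePositionPatient") and hasattr(ds, "pixel_array"):
            slices.append(ds)
    if len(slices) < 2:
        raise FormatError(f"{path}: no readable DICOM series found")
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    zs = np.array([float(d.ImagePositionPatient[2]) for d in slices])
    dz = np.diff(zs)
    if dz.min() <= 0 or (dz.max() - dz.min()) > 1e-3 * dz.mean():
        raise FormatError(f"{path}: inconsistent DICOM slice spacing")
    first = slices[0]
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    planes = []
    for d in slices:
        arr = d.pixel_array.astype(np.float64)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    vol = np.stack(planes, axis=-1)  # (rows=y, cols=x, z)
    vol = np.transpose(vol, (1, 0, 2))  # -> (x, y, z)
    units = str(getattr(first, "Units", "")).upper()
    if units == "BQML":
        vol /= 1000.0
        logger.info("DICOM units BQML converted to kBq/ml")
    spacing = np.array([col_mm, row_mm, float(dz.mean())])
    ipp = np.asarray(first.ImagePositionPatient, dtype=float)
    return PetImage(vol, spacing, ipp, meta={"source": str(path), "units": "kBq/ml"})


def read_image(path) -> PetImage:
    """Read a NIfTI-1 file or a DICOM series directory into a PetImage."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    return _read_nifti(path)


def export_masks(img: PetImage, masks: dict, path) -> Path:
    """Write sphere masks as a NIfTI label map (0 = background, 1..n = spheres)."""
    label = np.zeros(img.voxels.shape, dtype=np.int16)
    for i, d in enumerate(sorted(masks, reverse=True), start=1):
        label[masks[d].mask] = i
    return write_image(
        PetImage(label, img.spacing, img.origin, {"labels": sorted(masks, reverse=True)}),
        path,
        sidecar=False,
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one experiment run (YAML-serialisable)."""

    experiment: str
    seed: int = 0
    out_dir: str = "petharm_out"
    voxel_spacing_mm: tuple = (2.7, 2.7, 3.3)
    noise_level: float = 0.25
    noise_correlation_fwhm_mm: float = 4.0
    filter_widths_mm: tuple = DEFAULT_FILTER_WIDTHS_MM
    penalisations: tuple = DEFAULT_PENALISATIONS
    n_scanners: int = 6
    calibration_bias_sd: float = 0.03
    psf_fwhm_sd_mm: float = 0.3
    vary_voxels: bool = True
    ratios: tuple = (2.0, 5.0, 8.0, 10.0, 15.0)
    n_lesions: int = 24
    reference_label: str = "PSF_6.4"
    fill: dict = field(default_factory=lambda: DEFAULT_GA68_FILL.to_dict())
    phantom: dict | None = None

    _FIELDS = (
        "experiment seed out_dir voxel_spacing_mm noise_level "
        "noise_correlation_fwhm_mm filter_widths_mm penalisations n_scanners "
        "calibration_bias_sd psf_fwhm_sd_mm vary_voxels ratios n_lesions "
        "reference_label fill phantom"
    ).split()

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise InvalidParameterError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise InvalidParameterError("seed must be an integer")
        if self.experiment == "optimise" and not (self.filter_widths_mm or self.penalisations):
            raise InvalidParameterError("optimise needs a non-empty reconstruction grid")

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec.from_dict(self.phantom) if self.phantom else default_nema_spec()

    def fill_spec(self) -> FillSpec:
        return FillSpec.from_dict(self.fill)

    def digest(self) -> str:
        """Stable digest of everything that affects the numeric outputs."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - set(cls._FIELDS)
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("voxel_spacing_mm", "filter_widths_mm", "penalisations", "ratios"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# analysis chain and experiment presets
# ---------------------------------------------------------------------------

def analyse_acquisition(
    img: PetImage,
    spec: PhantomSpec,
    fill: FillSpec,
    labels: dict | None = None,
    with_ptv: bool = True,
) -> tuple[IQResult, list[dict]]:
    """Segment, measure and (optionally) profile one acquisition.

    Returns the IQResult plus one PTV record per sphere (spheres whose
    footprint is too small or whose surface is conical carry a
    not-measurable flag rather than a number).
    """
    labels = dict(labels or {})
    masks = segment_all_spheres(img, spec)
    battery = place_background_battery(img, spec, masks)
    peaks = {d: find_peak_roi(img, m) for d, m in masks.items()}
    iq = measure_iq(img, masks, battery, fill, peaks, labels=labels)

    ptv_rows: list[dict] = []
    if with_ptv:
        for d in sorted(masks, reverse=True):
            row = {"diameter_mm": d, **labels}
            try:
                res = mean_ptv(extract_profiles(img, masks[d]))
                row.update(
                    {
                        "shape": res.shape,
                        "measurable": res.measurable,
                        "ptv_mean": res.mean if res.measurable else np.nan,
                        "ptv_sd": res.sd if res.measurable else np.nan,
                    }
                )
            except ProfilesUnavailableError as exc:
                row.update(
                    {"shape": "undefined", "measurable": False,
                     "ptv_mean": np.nan, "ptv_sd": np.nan, "note": str(exc)}
                )
            ptv_rows.append(row)
    return iq, ptv_rows


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format="%.10g")
    return str(path)


def _write_json(obj, path: Path) -> str:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
    return str(path)


def run_experiment(config: RunConfig, out_root=None) -> dict:
    """Execute one experiment preset; returns a manifest of written outputs.

    Outputs land in ``<out_dir>/<experiment>-<digest>/`` so reruns with a
    different configuration never overwrite earlier results; rerunning
    the identical config and seed reproduces every numeric output.
    """
    spec = config.phantom_spec()
    fill = config.fill_spec()
    out = Path(out_root if out_root is not None else config.out_dir)
    run_dir = out / f"{config.experiment}-{config.digest()}"
    run_dir.mkdir(parents=True, exist_ok=True)

    outputs: dict[str, str] = {}
    runner = {
        "optimise": _run_optimise,
        "multicentre": _run_multicentre,
        "clinical": _run_clinical,
        "contrast_sweep": _run_contrast_sweep,
    }[config.experiment]
    try:
        runner(config, spec, fill, run_dir, outputs)
    except Exception as exc:
        raise type(exc)(
            f"[experiment={config.experiment} digest={config.digest()}] {exc}"
        ) from exc

    manifest = {
        "experiment": config.experiment,
        "seed": config.seed,
        "config": asdict(config),
        "config_digest": config.digest(),
        "outputs": outputs,
    }
    outputs["manifest"] = _write_json(manifest, run_dir / "manifest.json")
    return manifest


def _recon_grid(config: RunConfig) -> list[ReconConfig]:
    grid = [ReconConfig("psf", gaussian_fwhm_mm=w) for w in config.filter_widths_mm]
    grid += [ReconConfig("bpl", penalisation=b) for b in config.penalisations]
    return grid


def _run_optimise(config, spec, fill, run_dir, outputs) -> None:
    scanner = ScannerProfile(
        name="GE-710-like",
        voxel_spacing_mm=tuple(config.voxel_spacing_mm),
        noise_level=config.noise_level,
        noise_correlation_fwhm_mm=config.noise_correlation_fwhm_mm,
    )
    iq_frames, ptv_rows = [], []
    for recon in _recon_grid(config):
        logger.info("optimise: simulating %s", recon.label)
        img = simulate_acquisition(spec, fill, scanner, recon, seed=config.seed)
        iq, ptv = analyse_acquisition(
            img, spec, fill,
            labels={"recon_label": recon.label, "scanner": scanner.name,
                    "isotope": fill.isotope.name, "seed": config.seed},
        )
        iq_frames.append(iq.to_dataframe())
        ptv_rows.extend(ptv)
    outputs["iq_results"] = _write_csv(pd.concat(iq_frames, ignore_index=True),
                                       run_dir / "iq_results.csv")
    outputs["ptv_results"] = _write_csv(pd.DataFrame(ptv_rows), run_dir / "ptv_results.csv")


def _run_multicentre(config, spec, fill, run_dir, outputs) -> None:
    base = ScannerProfile(
        name="site",
        voxel_spacing_mm=tuple(config.voxel_spacing_mm),
        noise_level=config.noise_level,
        noise_correlation_fwhm_mm=config.noise_correlation_fwhm_mm,
    )
    jitter = JitterSpec(
        calibration_bias_sd=config.calibration_bias_sd,
        psf_fwhm_sd_mm=config.psf_fwhm_sd_mm,
        vary_voxels=config.vary_voxels,
    )
    recons = {
        "conventional": ReconConfig("conventional", gaussian_fwhm_mm=6.4),
        "advanced": ReconConfig("bpl", penalisation=800.0),
    }
    iq_frames, limit_tables, compliance = [], [], {}
    for family, recon in recons.items():
        ensemble = simulate_ensemble(
            spec, fill, recon, config.n_scanners, base, jitter, seed=config.seed
        )
        results = []
        for img, profile in ensemble:
            iq, _ = analyse_acquisition(
                img, spec, fill, with_ptv=False,
                labels={"recon_label": recon.label, "scanner": profile.name,
                        "family": family, "isotope": fill.isotope.name},
            )
            results.append(iq)
            iq_frames.append(iq.to_dataframe())
        limits = derive_limits(aggregate(results), k=2.0, family=family)
        limit_tables.append(limits.table)
        compliance[family] = {
            r.labels["scanner"]: check_compliance(r, limits, family).to_dict("records")
            for r in results
        }
    outputs["iq_results"] = _write_csv(pd.concat(iq_frames, ignore_index=True),
                                       run_dir / "iq_results.csv")
    outputs["limits"] = _write_csv(pd.concat(limit_tables, ignore_index=True),
                                    run_dir / "limits.csv")
    outputs["compliance"] = _write_json(compliance, run_dir / "compliance.json")


def _run_clinical(config, spec, fill, run_dir, outputs) -> None:
    lesions = generate_synthetic_lesions(
        n_lesions=config.n_lesions,
        betas=tuple(config.penalisations),
        reference_label=config.reference_label,
        seed=config.seed,
    )
    report = []
    for beta in config.penalisations:
        label = f"BPL_{beta:g}"
        for metric in ("suv_max", "suv_mean", "suv_peak"):
            a, b = lesion_pairs(lesions, label, config.reference_label, metric)
            ba = bland_altman(a, b)
            report.append(
                {
                    "comparison": f"{label} vs {config.reference_label}",
                    "metric": metric,
                    "n": ba.n,
                    "mean_log_diff": ba.mean_diff,
                    "loa_lower": ba.loa_lower,
                    "loa_upper": ba.loa_upper,
                    "n_outside": ba.n_outside,
                    "paired_t": ba.paired_t,
                    "paired_p": ba.paired_p,
                    "significant_5pct": bool(ba.paired_p < 0.05),
                }
            )
    outputs["lesions"] = _write_csv(lesions, run_dir / "lesions.csv")
    outputs["ba_report"] = _write_json(report, run_dir / "ba_report.json")


def _run_contrast_sweep(config, spec, fill, run_dir, outputs) -> None:
    scanner = ScannerProfile(
        name="sweep",
        voxel_spacing_mm=tuple(config.voxel_spacing_mm),
        noise_level=config.noise_level,
        noise_correlation_fwhm_mm=config.noise_correlation_fwhm_mm,
    )
    recon = ReconConfig("conventional", gaussian_fwhm_mm=6.4)
    bkg = fill.background_concentration_kbq_ml
    rows = []
    for ratio in config.ratios:
        sweep_fill = FillSpec(
            ratio * bkg, bkg, isotope=fill.isotope,
            fill_to_scan_min=fill.fill_to_scan_min,
            residual_factor=fill.residual_factor,
        )
        img = simulate_acquisition(spec, sweep_fill, scanner, recon, seed=config.seed)
        c_dc, _ = sweep_fill.concentrations_at_scan()
        for s in spec.spheres:
            row = {"ratio": ratio, "diameter_mm": s.inner_diameter_mm}
            try:
                from .segmentation import segment_sphere

                mask = segment_sphere(img, s)
                vals = img.voxels[mask.mask]
                row.update(
                    {"segmented": True,
                     "RC_mean": float(vals.mean()) / c_dc,
                     "RC_max": float(vals.max()) / c_dc}
                )
            except SegmentationError as exc:
                row.update({"segmented": False, "RC_mean": np.nan,
                            "RC_max": np.nan, "note": str(exc)})
            rows.append(row)
    outputs["contrast_sweep"] = _write_csv(pd.DataFrame(rows), run_dir / "contrast_sweep.csv")
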