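"""Quantify edge artifacts across reconstruction settings.

Sharp PSF-type reconstructions overshoot at activity boundaries (Gibbs
ringing): profiles through a sphere peak at the rim and dip at the
centre.  The peak-to-valley ratio (PTV) quantifies this; smoothing
(wider post filter w, larger penalisation beta) suppresses it toward 1.
"""

import petharm as ph
from petharm.profiles import extract_profiles, mean_ptv
from petharm.segmentation import segment_sphere

spec = ph.default_nema_spec()
fill = ph.DEFAULT_GA68_FILL
scanner = ph.ScannerProfile(voxel_spacing_mm=(2.0, 2.0, 2.0), noise_level=0.0)
sphere = spec.sphere_by_diameter(37.0)

print("37-mm sphere, mean PTV over six profiles (shape class):")
for recon in [ph.ReconConfig("psf", gaussian_fwhm_mm=w) for w in (2, 4, 5, 6.4)] + [
    ph.ReconConfig("bpl", penalisation=b) for b in (200, 400, 600, 800, 1000, 1200)
]:
    img = ph.simulate_acquisition(spec, fill, scanner, recon, seed=1)
    res = mean_ptv(extract_profiles(img, segment_sphere(img, sphere)))
    value = f"{res.mean:.3f} +- {res.sd:.3f}" if res.measurable else "not measurable"
    print(f"  {recon.label:>9}: {value}  ({res.shape})")

print(
    "\nPTV > 1 marks a rim-and-valley ('concave') artifact; it declines "
    "monotonically with smoothing and reaches ~1 at w = 6.4 mm / high beta."
)
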