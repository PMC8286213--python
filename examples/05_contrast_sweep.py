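"""Sphere-to-background ratio sweep: when does isocontour segmentation fail?

Refills the phantom at ratios from 2:1 to 15:1 and attempts the
50%-of-maximum isocontour delineation of every sphere.  At low contrast
the 50% level set of a small, blurred sphere falls below the background
level and the region merges with it — segmentation fails.
"""

import petharm as ph
from petharm.errors import SegmentationError
from petharm.segmentation import segment_sphere

spec = ph.default_nema_spec()
scanner = ph.ScannerProfile(voxel_spacing_mm=(2.0, 2.0, 2.0), noise_level=0.25)
recon = ph.ReconConfig("conventional", gaussian_fwhm_mm=6.4)

print(f"{'ratio':>6} " + " ".join(f"{d:>5.0f}" for d in spec.diameters()))
for ratio in (2, 5, 8, 10, 15):
    fill = ph.FillSpec(ratio * 2.4, 2.4)
    img = ph.simulate_acquisition(spec, fill, scanner, recon, seed=1)
    cells = []
    for s in spec.spheres:
        try:
            segment_sphere(img, s)
            cells.append("   ok")
        except SegmentationError:
            cells.append(" FAIL")
    print(f"{ratio:>4}:1 " + " ".join(cells))

print(
    "\nAt 2:1 only the largest spheres are delineable; from ~8:1 all six "
    "succeed — the rationale for the higher fill ratio used in Ga-68 studies."
)
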