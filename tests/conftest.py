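"""Shared fixtures: small synthetic phantom acquisitions (2-mm voxels).

Session-scoped so each simulated image is built once; all fixtures are
noiseless unless stated, keeping the suite deterministic and fast.
"""

import numpy as np
import pytest

import petharm as ph
from petharm.segmentation import SphereMask
from petharm.simulate import ground_truth_masks


@pytest.fixture(scope="session")
def spec():
    return ph.default_nema_spec()


@pytest.fixture(scope="session")
def fill():
    return ph.DEFAULT_GA68_FILL


@pytest.fixture(scope="session")
def scanner_2mm():
    return ph.ScannerProfile(voxel_spacing_mm=(2.0, 2.0, 2.0), noise_level=0.0)


@pytest.fixture(scope="session")
def identity_image(spec, fill):
    """Rasterised phantom with no blur, noise or bias (2-mm voxels)."""
    return ph.rasterize(spec, fill, (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def identity_masks(spec, identity_image):
    """Ground-truth interior masks (plateau voxels only) as SphereMask objects."""
    out = {}
    for d, m in ground_truth_masks(spec, identity_image, mode="interior").items():
        idx = np.argwhere(m)
        vals = identity_image.voxels[m]
        k = int(np.argmax(vals))
        out[d] = SphereMask(
            spec.sphere_by_diameter(d), m, float(vals[k]), tuple(int(i) for i in idx[k])
        )
    return out


@pytest.fixture(scope="session")
def blurred_image(spec, fill, scanner_2mm):
    """Conventional 6.4-mm reconstruction, noiseless: pure partial-volume case."""
    recon = ph.ReconConfig("conventional", gaussian_fwhm_mm=6.4)
    return ph.simulate_acquisition(spec, fill, scanner_2mm, recon, seed=1)


@pytest.fixture(scope="session")
def sharp_psf_image(spec, fill, scanner_2mm):
    """PSF reconstruction with a 2-mm filter: strong edge overshoot."""
    recon = ph.ReconConfig("psf", gaussian_fwhm_mm=2.0)
    return ph.simulate_acquisition(spec, fill, scanner_2mm, recon, seed=1)
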