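"""Derive multi-scanner specification limits and check compliance.

Simulates a six-scanner ensemble with inter-scanner variation
(calibration bias, resolution, voxel size), aggregates the recovery
coefficients across sites, derives mean +- 2 SD specification limits,
and checks each scanner against them — the harmonisation workflow of a
multi-centre trial.  The Ga-68 limits table shipped with the package is
shown for comparison.
"""

import petharm as ph
from petharm.io import analyse_acquisition

spec = ph.default_nema_spec()
fill = ph.DEFAULT_GA68_FILL
base = ph.ScannerProfile(noise_level=0.2)
jitter = ph.JitterSpec(calibration_bias_sd=0.03, psf_fwhm_sd_mm=0.3, vary_voxels=True)
recon = ph.ReconConfig("bpl", penalisation=800.0)

ensemble = ph.simulate_ensemble(spec, fill, recon, 6, base, jitter, seed=7)
results = [
    analyse_acquisition(img, spec, fill, with_ptv=False,
                        labels={"scanner": prof.name})[0]
    for img, prof in ensemble
]

limits = ph.derive_limits(ph.aggregate(results), k=2.0, family="advanced")
shipped = ph.LimitsTable.shipped_ga68()

print("RC_mean limits (mean +- 2 SD across the 6 simulated scanners):")
print(f"{'sphere':>8} {'derived':>16} {'shipped Ga-68':>16}")
for d in (37.0, 28.0, 22.0, 17.0, 13.0, 10.0):
    lo, hi = limits.bounds("advanced", "RC_mean", d)
    slo, shi = shipped.bounds("advanced", "RC_mean", d)
    print(f"{d:>6.0f}mm {lo:>7.3f}-{hi:<7.3f} {slo:>8.2f}-{shi:<7.2f}")

n_fail = sum(
    (~ph.check_compliance(r, limits, "advanced").passed).sum() for r in results
)
print(f"\nCompliance of the 6 scanners against their own derived limits: "
      f"{n_fail} violations.")
print("Derived bands reflect only the simulated inter-scanner variation; the "
      "shipped table carries the published multi-centre Ga-68 specifications.")
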