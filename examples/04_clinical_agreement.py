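"""Bland-Altman agreement between reconstruction variants on lesion SUVs.

Generates a synthetic 24-lesion PSMA cohort (13 prostate, 9 lymph node,
2 bone) measured under a PSF_6.4 reference and penalised-likelihood
reconstructions at beta = 200..1200, then tests each beta against the
reference: mean log-SUV difference, 1.96-SD limits of agreement and the
paired t test.
"""

import math

import petharm as ph
from petharm.clinical import generate_synthetic_lesions, lesion_pairs

lesions = generate_synthetic_lesions(seed=42)
print(f"{len(lesions.lesion_id.unique())} lesions x "
      f"{lesions.recon_label.nunique()} reconstructions\n")

print(f"{'comparison':>22} {'mean ratio':>10} {'LoA (ratio)':>16} {'outside':>8} {'p':>9}")
for beta in (200, 400, 600, 800, 1000, 1200):
    a, ref = lesion_pairs(lesions, f"BPL_{beta}", "PSF_6.4", "suv_max")
    ba = ph.bland_altman(a, ref)
    lo, hi = ba.ratio_limits()
    star = "*" if ba.paired_p < 0.05 else " "
    print(
        f"  BPL_{beta:<5} vs PSF_6.4 {math.exp(ba.mean_diff):>10.3f} "
        f"{lo:>7.3f}-{hi:<8.3f} {ba.n_outside:>5}/24 {ba.paired_p:>9.2g}{star}"
    )

print(
    "\n* = significant SUV difference at the 5% level. Low penalisation "
    "inflates SUVs; agreement with the smoothed PSF reference is reached "
    "around beta = 800-1000."
)
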