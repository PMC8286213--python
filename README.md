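# petharm

Quantitative harmonisation toolkit for Gallium-68 PET-CT phantom
studies: simulate NEMA IQ phantom acquisitions, measure recovery and
noise, quantify edge artifacts, derive multi-scanner specification
limits, and assess SUV agreement between reconstruction variants.

## Why

Multi-centre PET trials require quantitative values (SUVs, recovery
coefficients) to be comparable across scanners and sites.  For
F-18/FDG this is handled by established accreditation bands, but Ga-68
tracers (PSMA, DOTATATE) behave differently: the ~5× longer positron
range blurs small structures, and modern reconstructions — PSF
modelling and Bayesian penalised-likelihood (BPL, penalisation factor
β) — trade noise against resolution while introducing Gibbs-type edge
overshoot.  Harmonising them requires phantom-based metrics and
Ga-68-specific acceptance limits.  petharm implements that analysis
chain for physicists setting up or auditing such trials, together with
a fully controllable synthetic-data generator so every stage is
testable without scanner data.

## The metrics

For each sphere of the NEMA IEC body phantom (37, 28, 22, 17, 13,
10 mm), delineated by a 3D isocontour at 50% of its maximum:

* recovery coefficient  RC = C_m / C_dc, with C_m the hottest voxel
  (RC_max), the VOI mean (RC_mean) or the mean of a floating 1-cm³
  sphere at the hottest location (RC_peak), and C_dc the true
  decay-corrected concentration;
* contrast recovery  CRC = (C_m − C_bkg,m) / (C_dc − C_bkg,dc);
* background variability  BV_r = SD of the means of 60 background ROIs
  of diameter r, divided by their grand mean (360 ROIs total:
  6 sizes × 12 positions × 5 slices);
* image roughness  IR_r = mean within-ROI voxel coefficient of
  variation;
* peak-to-valley ratio  PTV = max along a profile / min in the central
  region — 1 for a clean flat-top, > 1 under edge overshoot;
* specification limits: mean ± 2 SD of each RC metric across scanners,
  with compliance checking against the shipped Ga-68 limits table;
* Bland–Altman agreement of log-transformed lesion SUVs with
  mean ± 1.96 SD limits and paired t tests.

## Worked example

```python
import petharm as ph
from petharm.io import analyse_acquisition

spec = ph.default_nema_spec()                    # the six-sphere phantom
fill = ph.DEFAULT_GA68_FILL                      # 19.9 / 2.4 kBq/ml
scanner = ph.ScannerProfile(name="site-A", noise_level=0.25)
recon = ph.ReconConfig("conventional", gaussian_fwhm_mm=6.4)

img = ph.simulate_acquisition(spec, fill, scanner, recon, seed=1)
iq, ptv = analyse_acquisition(img, spec, fill)
print(iq.to_dataframe()[["diameter_mm", "RC_max", "RC_mean", "RC_peak", "BV", "IR"]])
```

Running `python examples/01_simulate_and_measure.py` prints:

```
OSEM_6.4 at (2.7, 2.7, 3.3) mm voxels
  sphere  RC_max  RC_mean  RC_peak    BV%    IR%
    37mm   1.044    0.795    1.006    2.7    8.4
    28mm   1.003    0.722    0.941    3.4    8.0
    22mm   0.973    0.677    0.850    4.4    7.5
    17mm   0.783    0.536    0.618    5.4    6.9
    13mm   0.590    0.400    0.431    6.3    5.8
    10mm   0.388    0.256    0.274    6.7    5.4
```

Recovery falls with sphere size — the partial-volume loss that
motivates size-dependent acceptance bands — and BV/IR quantify the
background noise an acquisition would contribute to lesion
quantification.  The other examples cover edge-artifact suppression
across β and filter width (`02`), deriving mean ± 2 SD multi-scanner
limits and checking compliance (`03`), Bland–Altman SUV agreement on a
synthetic lesion cohort (`04`), and the sphere-to-background ratio
sweep showing where isocontour segmentation breaks down (`05`).

A thin CLI wraps the same functions:

```bash
petharm simulate --seed 1 --out sim_out/
petharm analyse sim_out/OSEM_6.4_seed1.nii --out analysis_out/
petharm run experiment.yaml            # optimise | multicentre | clinical | contrast_sweep
```

## Layout

```
src/petharm/
  phantom.py       phantom geometry, isotopes, fills, recon labels
  image.py         the PetImage voxel container
  simulate.py      synthetic acquisitions and multi-scanner ensembles
  segmentation.py  sphere VOIs, background battery, peak ROI
  metrics.py       RC / CRC / BV / IR
  profiles.py      1D profiles, PTV, surface shape classes
  harmonise.py     aggregation, specification limits, compliance, Welch test
  clinical.py      Bland-Altman, paired tests, synthetic lesion cohorts
  io.py            NIfTI/DICOM I/O, run configs, experiment presets
  cli.py           the petharm command-line interface
  data/limits_ga68_table2.csv   shipped Ga-68 specification limits
```

See `docs/methods.md` for the simulator's model and its limitations.
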