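# acrpet

Automated, quantitative analysis of the ACR-approved Jaszczak PET phantom
(Esser PET faceplate), aimed at physicists evaluating PET/MR and PET/CT
systems: attenuation-map generation for scanners without a usable CT μ-map,
high-resolution concentric-ring VOI sampling, direct estimation of the
effective in-image point-spread function from every cylindrical insert, and
bootstrap-based precision for any image-derived statistic.

## What it computes

The phantom is modelled parametrically (210 mm internal diameter, 190 mm
height, hot inserts ⌀25/16/12/8 mm at 2.5:1 contrast, cold air/water/Teflon
cylinders, six pie-sector sets of acrylic resolution rods) and voxelized
into μ-maps (511 keV, values 0.096/0.1036/0.117/0.148 cm⁻¹ for
water/nylon/acrylic/Teflon), activity maps, and label maps.

Each insert and rod is sampled with concentric ring VOIs on a 0.5 mm design
grid, giving the radial knife-edge response K(x) across each cylindrical
boundary.  K(x) is fitted with the four-parameter error-function model

    K(x) = A·erf(k(x − μ)) + b,

whose derivative is a Gaussian — the effective PSF — with amplitude
2Ak/√π (the maximum transition rate), σ = (k√2)⁻¹ and
FWHM = 2σ√(2 ln 2).  The inflection point μ estimates the imaged insert
boundary; contrast recovery is reported against well-counter reference
concentrations.  Fits predict annulus-averaged ring means and model the
cold 1.5 mm wall of fillable hot inserts explicitly (see
`docs/methods.md`).

Templates are aligned to images by two-stage rigid mutual-information
registration: STAGE I matches a non-attenuation-corrected appearance
template to the whole phantom; STAGE II automatically detects the
resolution-rod insert from summed axial profiles and registers it
separately, starting from a single approximate rotation angle.

A built-in simulator replaces list-mode reconstruction: activity maps are
misplaced, blurred with a known Gaussian PSF, scaled to a target count
level, and Poisson-resampled; voxel-wise Poisson redraws of the expected
counts provide bootstrap realizations for standard errors and for testing
whether registration adds variance beyond intrinsic PET noise.

## Worked example

```python
import acrpet
from acrpet.pet_simulator import SimulationConfig, simulate_recon

spec = acrpet.default_acr_spec()
templates = acrpet.make_insert_templates(spec)

cfg = SimulationConfig(psf_fwhm=4.0, total_counts=5e7, seed=1)
img = simulate_recon(spec, cfg)          # 2 mm grid, Bq/mL

for name in ("hot_25mm", "cold_water", "teflon"):
    t = templates[name]
    profile = acrpet.sample_template(img, t)
    fit = acrpet.fit_knife_edge(profile)
    m = acrpet.resolution_metrics(fit, t.edge_radius)
    c = acrpet.contrast_metrics(profile, reference_hot=8203.0, reference_bg=3281.0)
    print(f"{name:10s} FWHM {m['fwhm']:.2f} mm (valid={m['fwhm_valid']}) "
          f"offset {m['boundary_offset']:+.2f} mm  recovery {c['recovery_percent']:.1f}%")
```

prints

```
hot_25mm   FWHM 4.60 mm (valid=False) offset -0.20 mm  recovery 102.1%
cold_water FWHM 4.60 mm (valid=False) offset -0.13 mm  recovery 100.0%
teflon     FWHM 4.56 mm (valid=True) offset -0.12 mm  recovery 100.0%
```

The estimated effective FWHM (≈4.6 mm) is the 4 mm simulation PSF widened
by the 2 mm reconstruction grid; boundary offsets stay well inside a voxel,
and contrast recovers fully for the large inserts at this count level.  The
`valid` flag applies the width rule: FWHM is only trusted when the profile
samples at least two FWHM beyond the boundary, which at 4.6 mm holds for
the Teflon template (rings to 23 mm around a 12.5 mm edge) but not for the
walled inserts whose effective edge sits further out.  The reference
concentrations correspond to the standard fill: 8.3 MBq in 1 L for the
inserts and 18.7 MBq in 5.7 L for the background (8203 and 3281 Bq/mL, a
2.5:1 ratio).

A config-driven CLI wraps the same pipeline:

```bash
acrpet build    --config run.yml   # mu-map, activity map, all templates
acrpet simulate --config run.yml   # synthetic NAC/QNT images + bootstrap
acrpet analyze  --config run.yml   # registration, fits, metrics, report
```

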