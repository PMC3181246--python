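# crmquant

Quantitative analysis of 3D collagen-matrix structure and remodeling from
confocal reflection microscopy (CRM), with a synthetic fiber-network
generator that makes every measurement testable against known ground
truth.

## The problem

Cells embedded in 3D collagen gels remodel their matrix — depositing new
fibers, degrading existing ones, aligning them. CRM images the fibrous
network label-free, and matrix remodeling can be tracked over days through
four structural metrics:

* **fibril fraction** — the fraction of the imaged volume (or of each 2D
  slice) occupied by binarized collagen;
* **pore size** — background run lengths between fiber crossings along
  horizontal, vertical and diagonal line profiles through the binarized
  center slice, in µm;
* **fiber length and diameter** — per-object morphometry from the 3D
  skeleton (longest geodesic path) and the Euclidean distance transform
  (2 × median on-skeleton radius);

summarised per condition with **bias-corrected, accelerated (BCa)
bootstrap 95% confidence intervals** (≥5000 resamples; the metric
distributions are far from normal, so no parametric tests are used).
Gelatin-zymogram densitometry (cleared-band pixel counts normalized by
cell density) and power-law fits of rheometry sweeps (G = a·f^b,
evaluated at 10 Hz) quantify proteolytic activity and gel stiffness beside
the imaging pipeline.

Because no real image stack ships with the package, a first-class
synthetic module generates collagen-like fiber networks (straight
cylinders, known union volume fraction), evolves them under remodeling
operators, and renders CRM-like stacks — Gaussian PSF, read noise, and the
CRM *blind spot* (fibers oriented along the optical axis reflect nothing,
inflating apparent pore size). Every estimator is validated by parameter
recovery against this generator.

## Worked example

```python
import crmquant as cq
from crmquant.experiment import calibrate_threshold

# ground-truth network: 15% fiber volume fraction in a 40x40x20 um box
net = cq.generate_network(concentration_label=3, target_volume_fraction=0.15,
                          box=(40.0, 40.0, 20.0), seed=7)

# calibrate the binarization threshold on a phantom of known occupancy
imaging = {"box": [40.0, 40.0, 20.0], "voxel_size": [0.25, 0.25, 0.5],
           "psf_sigma": [0.15, 0.35], "noise_sd": 2.0,
           "blind_spot_half_angle": 0.0, "base_intensity": 100.0}
thr = calibrate_threshold(imaging, reference_fraction=0.15, seed=11)

# render a CRM stack and measure it
cfg = cq.RenderConfig(voxel_size=(0.25, 0.25, 0.5), stack_depth=20.0,
                      noise_sd=2.0, seed=7, lateral_extent=(40.0, 40.0))
stack = cq.render_crm(net, cfg)
binary = cq.binarize(stack, method="fixed", fixed_value=thr)
print("fibril fraction:", round(cq.fibril_fraction(binary), 4))

mean_pore, runs = cq.pore_size_summary(cq.pore_runs_center_slice(binary))
ci = cq.bca_ci(runs, statistic="mean", n_boot=5000, seed=7)
print("mean pore:", round(mean_pore, 2), "um,",
      "BCa CI [{:.2f}, {:.2f}]".format(ci.lower, ci.upper))

fit = cq.fit_power_law(cq.RheologySweep(
    (0.1, 0.3, 1.0, 3.0, 10.0), (201.0, 215.0, 240.0, 262.0, 285.0)))
print("G = {:.1f} * f^{:.3f}; G(10 Hz) = {:.1f} Pa".format(
    fit.prefactor, fit.exponent, fit.modulus_at_10Hz))
```

Output:

```
fibril fraction: 0.1413
mean pore: 10.39 um, BCa CI [6.13, 18.96]
G = 239.1 * f^0.078; G(10 Hz) = 286.0 Pa
```

The measured fibril fraction (0.141) recovers the generator's true
occupancy (0.150) through the calibrated threshold; the pore CI is wide
because a single center slice contributes only 9 interior runs — the
experiment pipeline pools runs across stacks (and `pore_runs_stack` pools
across slices) before bootstrapping. The rheology sweep here is a typical
3 mg/ml-like collagen response; the fit reports the modulus the power law
implies at 10 Hz.

## Command line

```bash
crmquant simulate --concentration 3 --volume-fraction 0.2 \
    --days 1,3,5,7 --seed 7 --out sim/            # stacks + truth JSON
crmquant example-config > experiment.yaml          # editable design
crmquant analyze --config experiment.yaml --out results/
crmquant fit-rheology sweep.csv                    # power-law fit JSON
```

`analyze` runs the full design (conditions × replicate gels × stacks ×
days), writes `measurements.csv` (long format), `metrics.csv` (per-stack),
`group_cis.csv`, `comparisons.csv` (CI-overlap flags) and a JSON manifest
that reproduces the run byte for byte from its master seed.

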