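# adipospec

Label-free spectral lipidomics of adipocytes from Raman and FTIR
hyperspectral imaging — as a tested, synthetic-data-driven pipeline.

Vibrational microspectroscopy can map the chemistry of single fat cells
without staining: lipid droplets, the thin perilipidic zone around them,
the nucleus and cytoplasm each have characteristic bands, and band-area
ratios report lipid-class content.  Two classical calibrations turn ratios
into chemistry:

* **acyl chain length** from the CH2/CH3 stretching ratio
  A(2852)/A(2954) cm⁻¹, which for a saturated triacylglycerol with N total
  acyl carbons equals N/3 − 2;
* **unsaturation degree** (mean C=C bonds per acyl chain) from the Raman
  I(1660)/I(1451) ratio, calibrated on the C18 fatty-acid series
  (stearic → α-linolenic).

Since no public hyperspectral data accompany this workflow, the package
ships a first-class phantom generator: virtual adipocytes with known
compartment masks and molecular composition, rendered into Raman
(550–3100 cm⁻¹, 3 cm⁻¹ step, 0.5 µm pixels) or FTIR cubes (900–3700 cm⁻¹,
4 cm⁻¹ step, 5.5 µm pixels) and corrupted with the artifacts the
preprocessing stage exists to remove (fluorescence baselines, noise,
cosmic spikes, Mie scattering).  Every stage is tested against that ground
truth.  It is aimed at spectroscopists prototyping cell-imaging analysis
chains and at method developers who need a controlled forward model.

## What is in the box

| module | contents |
| --- | --- |
| `adipospec.core` / `.io` | spectra, cubes, band windows, integration; ENVI-style, CSV and HDF5 I/O |
| `adipospec.library` / `.phantom` | pure-component band library with group-counting conventions; cell layouts, rendering, corruption with artifact registry |
| `adipospec.preprocess` | despiking, polynomial + concave rubber-band baselines, Savitzky–Golay, vector normalization, amide-I quality mask, PCA denoising, RMieS-EMSC scattering correction |
| `adipospec.segment` | k-means (KMCA) and Ward/D-value hierarchical (UHCA) segmentation, marker-band compartment naming, droplet instance tables |
| `adipospec.metrics` | the seven band-ratio metrics, chain-length and unsaturation calibrations |
| `adipospec.stats` | NIPALS PCA, one-way ANOVA + Tukey-Kramer, the synthetic fixative-comparison experiment |
| `adipospec.cli` | `adipospec simulate\|preprocess\|segment\|metrics\|compare` |

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
import adipospec as a
from adipospec.preprocess import postprocess_mean_spectrum

cube, layout, registry = a.simulate_cube("raman", seed=42)
print(f"cube: {cube.height}x{cube.width} px, {len(cube.axis)} channels, "
      f"{len(layout.ld_instances)} droplets, {len(registry['spikes'])} cosmic spikes")

clean, log = a.preprocess_raman_cube(cube)
print(f"despiked {log['spike_channels_replaced']} channels")

result = a.assign_compartments(a.kmca(clean, k=4, seed=0))
ari = adjusted_rand_score(layout.label_map().ravel(), result.label_map.ravel())
print(f"classes: {sorted(result.class_names.values())}")
print(f"adjusted Rand index vs ground truth: {ari:.3f}")

model = a.build_unsaturation_calibration()
ld_mean = postprocess_mean_spectrum(result.spectrum_for("lipid_droplet"))
pred = a.unsaturation_from_spectrum(ld_mean, model)
print(f"LD unsaturation: {pred.value:.3f} C=C per acyl chain "
      f"(ground truth 0.42)")
```

prints

```
cube: 64x64 px, 851 channels, 19 droplets, 79 cosmic spikes
despiked 79 channels
classes: ['cytoplasm', 'lipid_droplet', 'nucleus', 'perilipidic_area']
adjusted Rand index vs ground truth: 1.000
LD unsaturation: 0.420 C=C per acyl chain (ground truth 0.42)
```

Reading: the generator injected 79 single-channel cosmic spikes and the
despiker removed exactly those; k-means on the baseline-corrected cube
recovered all four ground-truth compartments perfectly (ARI 1.0); and the
calibrated 1660/1451 ratio of the lipid-droplet class mean returned the
composition's true mean unsaturation of 0.42 C=C bonds per acyl chain.

The same flow works for FTIR (`simulate_cube("ftir", ...)`,
`preprocess_ftir_cube`, `uhca`), and `fixative_experiment` runs a complete
two-group comparison (simulate → preprocess → segment → metrics →
ANOVA/Tukey + PCA) against an injected-perturbation registry.

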