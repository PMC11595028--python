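# Methods

`adipospec` implements a label-free vibrational spectral-lipidomics
workflow for adipocytes.  Because no real hyperspectral
data are available, the package is built around a synthetic-phantom module
that generates Raman and FTIR cubes of virtual lipid-laden cells with full
ground truth; every downstream stage (preprocessing, segmentation,
band-ratio metrics, group statistics) is validated against that ground
truth.

## Spectral model

Every molecular component (fatty acids, triacylglycerols, cholesteryl
esters, phospholipids, alpha/beta protein pools, nucleic acids,
cytochromes, sugars) is a list of analytic bands per modality
(pseudo-Voigt, eta = 0.5; FWHM 12 cm^-1 Raman, 20 cm^-1 FTIR by default;
positions follow the standard assignments: 2852/2954 cm^-1 CH2/CH3
stretches, 1743 cm^-1 ester C=O, 1660 cm^-1 C=C stretch, 1451/1465 cm^-1
CH deformations, 780-800 cm^-1 nucleic acids, 750/1316/1585 cm^-1
resonance-enhanced cytochrome bands, 1620-1680 cm^-1 amide I).

Lipid band areas follow a group-counting convention:

* CH2 and CH3 stretching areas are proportional to the group counts with a
  common cross-section, so a saturated TAG with N total acyl carbons has
  A(2852)/A(2954) = (N - 6)/3 = N/3 - 2 exactly;
* the C=C stretching area is proportional to the number of C=C bonds while
  the CH deformation area is fixed *per acyl chain*, so I(1660)/I(1451)
  equals the mean number of C=C bonds per chain exactly.

These conventions make the two calibrations (chain length from 2852/2954;
unsaturation from 1660/1451) exactly linear on ideal spectra, so any
deviation measured downstream is attributable to the pipeline, not to the
phantom.  Free fatty acids are modelled as esterified acyl equivalents (the
neutral-lipid pool of a droplet), so every chain also carries an ester
band.  Ideal calibration standards are rendered with Gaussian bands; at the
band separations involved, mutual overlap is then below double precision
and the linear identities hold to ~0.1% (limited only by the spline
quadrature of the integration windows).

## Phantom geometry and composition

A virtual cell fills the field of view and contains one elliptical nucleus
(area ~ N(60, 8^2) um^2), disc-shaped lipid droplets with log-normal areas,
a one-pixel perilipidic shell around every droplet, and cytoplasm.  Raman
default: 32 um field at 0.5 um pixels, droplet areas median 3 um^2
(log-sd 0.8, right tail into tens of um^2).  FTIR default: 700 um field at
5.5 um pixels; here the phantom models a mature adipocyte with large
coalesced droplets (median 700 um^2), because sub-pixel droplets would make
the droplet class unobservable at FPA resolution.

Default lipid-droplet composition (mole fractions): stearic 0.281,
palmitic 0.262, oleic 0.394 acyl pools plus minor TAG 48:1 (0.037),
CE 14:1 (0.013) and PL 34:1 (0.013).  The minor fractions are fixed so the
pooled unsaturation is exactly 0.42 C=C per chain — the ground truth the
end-to-end readout must recover.  The perilipidic shell is
phospholipid/beta-sheet/cytochrome/sugar-rich; its exact fractions are free
parameters of the phantom (no quantitative composition is available) and
are documented in `phantom.default_composition`.

Rendering: per-pixel composition-weighted component sum, blurred per
channel with a Gaussian PSF specified by its FWHM (0.3 um Raman, 6 um
FTIR — the lateral resolutions of the two instruments).  FTIR cubes get a
gain of 4.0 (so in-cell amide-I absorbance sits in the 0.2-1 range probed
by the quality test) and a 0.5 x cytoplasm overlay on every in-cell pixel,
modelling that transmission FTIR integrates the whole cell depth while
confocal Raman sections optically.  Without that overlay, droplet pixels
would fail the amide-I quality test, which contradicts how real FTIR maps
of adipocytes behave.

Corruption (all randomness from one seed): smooth per-pixel polynomial
baselines (fluorescence-like, degree 3, ~0.5 x mean signal for Raman),
Gaussian noise (3% / 2% of mean signal), single-channel cosmic spikes
(2% of Raman pixels, 10 x local max; FPA detectors get none) and, for
FTIR, van de Hulst Mie extinction Q(rho) = 2 - (4/rho) sin rho +
(4/rho^2)(1 - cos rho), rho = 4 pi r (n - 1) nu.  Extinction multiplies
transmittance and therefore *adds* in absorbance, which is how it is
applied.  The Mie radius/index/amplitude fields are spatially smooth and
the amplitude follows droplet morphology (droplets are the physical
scatterers); amplitudes of 0.05-0.15 OD model film-like fixed cells.
Every injected artifact is returned in a registry so tests can score
recovery exactly.

What the phantom does *not* emulate: physically rigorous Raman cross
sections, photobleaching, detector nonlinearity, water-vapor lines, 3D
sectioning, and cell-to-cell biological heterogeneity beyond optional
composition jitter.  Passing tests therefore demonstrate correctness of the
algorithms under a controlled forward model, not instrument-grade
performance on real tissue.

## Preprocessing

Raman, per pixel: (1) despiking — channels whose residual from a
running median (window 3) exceed 8 x a robust scale are replaced by the
median.  The scale is the MAD of the residuals floored at 5% of the
spectrum's peak-to-peak range; the floor encodes that genuine bands never
produce running-median residuals near the spectral range, and keeps sharp
band tops untouched while cosmic spikes remain orders of magnitude above
threshold.  (2) a 3rd-order polynomial baseline fitted as a lower envelope
(iteratively reweighted, 10 passes, weight 0.05 above the fit).  Class
mean spectra extracted after clustering additionally get a concave
rubber-band baseline (10 iterations; each pass bends the spectrum convex
with a parabolic sag that halves per iteration before taking the lower
convex hull — the estimate never exceeds the spectrum, so nonnegative
spectra stay nonnegative), Savitzky-Golay smoothing (11 points, order 2),
cropping to 500-3100 cm^-1 and vector normalization.

FTIR, per pixel: amide-I quality test (max absorbance in 1620-1680 cm^-1
>= 0.2; max-in-window chosen over the integral — both are defensible
readings of the vendor test), PCA noise reduction (13 components),
Savitzky-Golay smoothing (13 points), vector normalization.  Scattering
correction (RMieS-EMSC) is applied to the class mean spectra extracted
after clustering: a 10 x 10 database of van de Hulst curves over r in
[2, 8] um, n in [1.1, 1.5] is reduced to its first 7 principal directions,
each spectrum is regressed on [constant, linear term, reference,
components], and the corrected spectrum is the reference plus the residual
rescaled by the reference coefficient.  This is the one-pass EMSC variant
with a Mie basis, not the full iterative resonant algorithm with a complex
refractive index; the iteration count is configurable and the difference
matters mainly for strongly resonant (highly absorbing) samples.

Numerical notes: band integration is trapezoidal on the native grid with
window endpoints snapped to the nearest channels for chemical maps, but
quantitative band *ratios* integrate a cubic spline between exact window
bounds — on a 4 cm^-1 grid, snapped 2852/2954 windows end up 16 vs 20 cm^-1
wide and would bias the chain-length ratio by ~6%.  With the
`linear_endpoints` mode the chord between the window endpoints is
subtracted first, so affine spectra integrate to exactly zero.

## Segmentation

Raman cubes are clustered by k-means (k = 4 by default; k-means++ from an
explicit seed, 10 restarts, tolerance 1e-6) on the per-pixel spectra; FTIR
cubes by Ward-linkage hierarchical clustering on D-values,
D = (1 - r) x 1000 with r the Pearson correlation over the 900-1800 and
2800-3050 cm^-1 regions (correlation tolerates the residual scattering
baseline).  Cubes beyond 5000 in-mask pixels are subsampled for the
linkage and remaining pixels joined by correlation to the class means.
Labels are renamed deterministically from marker bands: lipid droplet =
largest CH-stretch (Raman) or ester (FTIR) integral; nucleus = largest
780-800 cm^-1 integral (Raman only — at FTIR resolution the nucleus spans
~2 FPA pixels and is folded into cytoplasm); cytoplasm = largest
amide-I-to-lipid ratio; the remaining class is the perilipidic area.  Ties
break by class size.  Droplet instances are 8-connected components
(discs rendered on coarse grids fragment under 4-connectivity).

## Metrics and calibrations

Seven ratio metrics (locally baselined band areas, half-width 8 cm^-1
Raman / 10 cm^-1 FTIR around the named centers): TAGs 1743/1465, CEs
1178/1465, total lipids (2852+2954)/1465, PLs 1129/1451, UFAs 1660/1451,
chain length 2852/2954, cytochromes (1585+1316+750)/1451.  Calibrations
are stored as ratio-on-property regressions and inverted for prediction;
predictions outside the training range (widened by 10% of its span) are
flagged as extrapolation but still returned.  The droplet unsaturation
readout uses the segmented droplet class *mean* spectrum, not per-pixel
values.  Band cross-talk caveat: the 1306 cm^-1 C=C band shoulders the
1316 cm^-1 cytochrome window, so strong unsaturation changes bleed
slightly into the cytochrome metric — visible in the perturbation
experiment and inherent to band-ratio lipidomics.

## Group statistics

PCA is sequential NIPALS (tolerance 1e-10 on the score vector, up to 5000
iterations — plain power iteration needs more than a few hundred steps for
near-degenerate eigenpairs; sign convention: largest-magnitude loading
element positive) over the fingerprint + CH regions, excluding the
1800-2800 cm^-1 silent region.  An optional 20-segment cross-validated Q2
per component is reported as a diagnostic only.  Group comparison is
one-way ANOVA with Tukey-Kramer pairwise contrasts (studentized-range
p-values, unequal-n form, tiers 0.05/0.01/0.001); zero within-group
variance raises an exact-separation flag.

The fixative experiment simulates two treatment groups end to end:
n = 15 cells per group per modality at desk scale (16 um Raman and 176 um
FTIR fields, 32 x 32 pixels each, ~20 s per experiment), with 5% log-normal
composition jitter between cells, optional band-family attenuations per
compartment per group (the defaults bleach cytochromes in one group and
attenuate unsaturated/cytoplasmic lipid signal in the other, leaving the
droplet TAG/CE core intact), and a report that checks every metric x
compartment cell for a group effect against the injected-perturbation
registry.

## Known limitations

* The phantom's perilipidic composition and all corruption magnitudes are
  plausible but invented; only the droplet composition is pinned to a
  reported value (0.42 C=C per chain).
* The rubber-band sag schedule (parabolic, halving) is one of several
  vendor-style conventions; peak-area recovery is verified to <= 2% on
  convex, concave and flat baselines.
* RMieS here corrects the dominant smooth scattering distortion; resonant
  band-shape distortions of strongly absorbing samples are out of scope.
* Savitzky-Golay smoothing at the default 11 points on a 3 cm^-1 grid
  visibly attenuates 12 cm^-1-wide bands; equal-width band ratios are
  unaffected (both bands attenuate alike), which is why the calibrated
  readouts remain accurate.
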