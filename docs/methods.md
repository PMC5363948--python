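# Methods

`osteospec` analyses vibrational hyperspectral images of compact human bone
to characterize diagenetic change over post-mortem intervals (PMI) from one
day to over a millennium. Because raw spectra of the kind of cadaveric and
archaeological material this addresses are essentially never publicly
deposited, the package ships a synthetic generator that plays the role of
the instrument: every analysis operation is developed and validated against
cubes with exact ground truth. This note records the models, the parameter
choices that were genuinely open, and what the synthetic validation does and
does not demonstrate about real bone.

## Data model

A `HyperspectralCube` is a `(height, width, n_channels)` block of
absorbance-like (FTIR) or counts-like (Raman) intensities on a strictly
monotonic wavenumber axis, plus acquisition metadata (modality, lateral
pixel pitch in μm, sample id, PMI in days). Axes arriving in descending
instrument order are flipped to ascending storage; all window arguments are
`(lo, hi)` regardless. Modality defaults mirror typical instrumentation:

| modality   | axis (cm⁻¹)      | spacing | pitch |
|------------|------------------|---------|-------|
| reflection | 600–4000         | 2       | 20 μm |
| atr        | 600–4000         | 2       | 10 μm |
| raman      | 0–1776 (shift)   | 6       | 1 μm  |

Cubes round-trip through a self-describing container: a text header
(`key=value` lines including the full axis) followed by a dense
little-endian float64 payload in C order; the format is documented in
`spectral_core` so independent code can read it. Reflection spectra are
analysed as recorded (no Kramers–Kronig transform).

## Synthetic bone

**Spatial structure.** A tissue template places `n_osteons` non-overlapping
discs (rejection sampling, seeded) on an interstitial background: a central
Haversian canal (radius 3 px), a lamellar annulus (to 9 px) and a thin
cement-line ring (1.5 px). Each of the four classes carries a weight per
chemical component class (mineral, carbonate, protein, carbohydrate,
lipid). Canals hold lipid-rich soft-tissue remnant and no mineral;
interstitial bone is slightly more mineralized and organics-poorer than
osteonal lamellae; cement lines are hypomineralized, protein/carbohydrate-
rich and lipid-poor. The weights were chosen once so that, after vector
normalization, the four classes have the contrast hierarchy seen in real
segmentations: canals and cement lines are spectrally far from everything,
while lamellae and interstitial bone are the closest pair — which is why a
3-cluster cut merges the two large bone compartments (poor template
agreement) and the histo-anatomy only resolves at k = 4.

**Spectra.** Each pixel spectrum is a sum of pseudo-Voigt bands (fixed
50/50 Gaussian–Lorentzian mixing) from a per-modality band library covering
the standard bone assignments: ν₁–ν₄ phosphate, B-type carbonate,
amide I/II/III, C–H deformation/stretch, carbohydrate C–O, plus a lipid
CH₂ twist in Raman. Band amplitude = base amplitude × tissue-class weight ×
a PMI factor.

**Diagenesis law.** With t in years:

- organic and carbonate classes:
  `A(t) = base · (floor + (1 − floor) · exp(−t/τ_class))`
- mineral: `A(t) = base · (1 + g · log10(1 + t))`

Defaults: τ_protein = 80 y, τ_carbohydrate = 20 y, τ_lipid = 8 y,
τ_carbonate = 1.2 y, floor = 0.02, mineral gain g = 0.15 per decade. These
are *calibration choices*, not measurements: no quantitative decay rates
are available for this material, so the constants are set — once, before
freezing the test suite — such that the default pipeline exhibits the
qualitative diagenetic signatures reported for real bone series: carbonate
detectable at 3 years but not at 25, visible organic depletion of
archaeological samples, strictly monotone ratio trends. The mineral-growth
log law encodes slow diagenetic mineral uptake from the burial environment.

**Noise and interference.** Per pixel: additive Gaussian noise
(σ = 0.006 a.u.), signal-proportional shot-like noise (scale 0.01), a
smooth polynomial baseline (default linear in wavenumber), and — for the
FTIR modes only — an adsorbed-water bending band (δH₂O, 1640 cm⁻¹, FWHM
80 cm⁻¹) whose amplitude varies pixel-to-pixel (mean 0.1, sd 0.08,
clipped at zero). The water band overlaps amide I and is the package's
explicit model of why Raman data separate cohorts more cleanly than FTIR:
Raman of bone is essentially water-free, FTIR is not. One per-modality
quality factor (reflection 2.5×, ATR 1.5×, Raman 1×) scales all
non-idealities, encoding the relative signal quality of the three channels.
The six-sample default cohort (PMIs 1 day, 3, 25, 85, 760, 1145 years; four
forensic, two archaeological; archaeological dating ranges collapsed to
midpoints because trend statistics need point values) derives all
randomness from one master seed via named substreams.

## Preprocessing

- **Baseline**: rubberband (lower convex hull of the (ν, intensity) point
  set, monotone-chain construction, subtracted per spectrum). Parameter-free
  and exactly invariant to added affine trends.
- **Smoothing**: Savitzky–Golay, default window 9 channels, order 2
  (reproduces polynomials of degree ≤ 2 exactly).
- **Atmospheric masks**: CO₂ 2300–2400 cm⁻¹ and water vapour
  1800–1900 cm⁻¹ for FTIR; none for Raman. Masked channels are *removed*,
  not zeroed, so norms and integrals run over retained channels only.
- **Normalization**: vector (unit Euclidean norm) over a stated window,
  default the full axis; out-of-window channels are scaled by the same
  factor.
- **Despiking** (Raman only): modified z-score of channel first
  differences; flagged channels are rebuilt by linear interpolation, and a
  spectrum with more than 5% flagged channels is rejected as not a
  cosmic-ray pattern.

## Chemical maps and detection

A chemi-map integrates each pixel's intensity over a band window with the
trapezoid rule on the native grid (no fitting), optionally after
subtracting the chord between the window's endpoint anchors (anchor = mean
of the first/last `endpoint_channels` channels; 1 reproduces the classic
two-point chord, the pipeline uses 3 for noise-robust anchors).

Detection is SNR-based: each map records the exact standard error of its
own estimator per unit of channel noise — the trapezoid quadrature weights
plus, when a chord is subtracted, the propagated anchor variance. SNR is
the integral divided by (σ̂ × that factor), with σ̂ estimated from the data
as a MAD of channel first-differences inside a declared band-free region
(Raman 20–380 cm⁻¹; FTIR 2000–2280 cm⁻¹) — unrestricted differences are
biased upward by band slopes and shot noise. A pixel is detected at
SNR ≥ 3; a *sample* is detected when at least 5% of its mineralized-tissue
pixels (non-canal) pass, which guards against salt-and-pepper false
positives. Both thresholds are configurable. Note the naive standard error
σ√n·Δν would understate the chord-subtracted estimator's noise by roughly
half and inflate the false-positive rate past the 5% spatial rule.

## Ratios

- MINCON (mineral content ratio) = ν₄PO₄ peak height / amide I peak height.
- OMR (organic-to-mineral ratio) = CH-aliphatic peak height (2800–3000 cm⁻¹
  FTIR; 1446 cm⁻¹ CH₂ for Raman) / phosphate peak height (1042 cm⁻¹ FTIR,
  957 cm⁻¹ Raman).

Peaks are windowed maxima (heights, not areas — an area variant exists
behind a flag but is unvalidated), read after a two-point chord baseline.
One documented exception: the FTIR ν₄PO₄ window (550–610 cm⁻¹) is clipped
by the 600 cm⁻¹ detector cutoff, leaving only the band's convex decaying
tail — which lies *on* any chord or lower hull drawn beneath it, so a local
baseline would read it as identically zero. Edge-clipped windows therefore
fall back to the raw windowed maximum (a warning is logged). The residual
background under that maximum does not depend on PMI, so trend statistics
are unaffected; absolute FTIR MINCON values, however, are offset by it and
should be compared only within an instrument configuration.

Cohort ratios are computed on the mean spectrum over mineralized-tissue
pixels (ratio of a mean spectrum, not mean of pixel ratios, which is
unstable when pixel denominators approach zero). Raman rows carry MINCON
only by default. Trends against PMI use Spearman rank correlation with an
*exact* permutation null for n ≤ 8 (all n! orderings enumerated; a
perfectly monotone six-point series gives two-sided p = 2/720 ≈ 0.0028);
ties in PMI take midranks and are noted.

## Segmentation

Pixels are preprocessed by a declared recipe (default: rubberband baseline,
then vector normalization) and clustered:

- **K-means**: Lloyd iterations, greedy farthest-point seeding from the
  given seed, best of 4 restarts by within-cluster sum of squares.
- **HCA**: Ward linkage on Euclidean distances of 1000 seeded-random anchor
  pixels (full-linkage cost on every pixel is quadratic and was rejected);
  the dendrogram is cut at k and remaining pixels join the nearest
  anchor-cluster centroid.

Labels are canonically renumbered by descending cluster size so maps are
comparable across reruns. Agreement with the generator template is the
adjusted Rand index. Distance/linkage choices (Euclidean on normalized
spectra, Ward) are the de-facto standard in IR imaging; they are declared,
not inferred from any particular instrument software.

## PCA and cohort separation

Per modality, 5 tissue pixels per sample (30 spectra) are selected — by
default uniformly among pixels whose mineral-band SNR ≥ 3 (estimated noise,
no ground truth needed); a template-based strategy exists when truth is
available. Spectra are cropped to the informative region (1700–750 cm⁻¹ for
reflection/ATR, 1700–300 cm⁻¹ for Raman), rubberband-corrected and vector
normalized, then decomposed by mean-centered SVD. Loadings carry a
canonical sign (largest-magnitude coefficient positive) so scores are
backend-reproducible. Forensic-vs-archaeological separation is the
silhouette coefficient of the two-label partition in the PC1–PC2 plane:
bounded in [−1, 1], scale-free, and exactly the visual notion of
"well-separated score-plot clusters". One PCA model is fitted per modality
(pooling modalities is not meaningful on different axes).

## Problem sizes and numerical choices

Default cubes are 64 × 64 pixels with 3 osteons — a desk-scale stand-in for
full instrument fields, chosen so an entire cohort (18 cubes, three
modalities) generates in seconds and the full pipeline in minutes on one
CPU. Tolerances: container round-trip exact in metadata and ≤ 1e-12 in
data; normalization idempotence/scale-invariance ≤ 1e-12; rubberband
affine-invariance ≤ 1e-9; PCA scores vs an independent power-iteration
oracle ≤ 1e-6 up to sign. Degenerate inputs raise typed errors
(zero-norm pixels, empty masks, non-positive ratio denominators —
the last signalling a fully degraded organic phase, which cohort tables
record as flagged rows rather than exceptions). Spearman permutation ties
are counted with a 1e-12 slack toward the observed statistic.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the *pipeline* is correct and
self-consistent: it recovers planted decay constants (≤ 1% noise-free,
≤ 15% at default noise from 12-point PMI grids), finds the planted
four-cluster histo-anatomy at exactly k = 4, reproduces the planted
carbonate change-point at 3 years, yields strictly monotone ratio trends,
and ranks Raman as the best-separating modality under the modelled water
interference. None of this validates the *biology*: real diagenesis is not
single-exponential, depends strongly on burial environment (none of the
find-spot covariates are modelled), real bands shift and broaden with
crystallinity, ATR penetration depth and reflection distortions are not
modelled, and real osteons are neither circular nor uniform. The generator
is a test harness with known truth, not a forward model of bone chemistry.

Known limitations: no vendor file formats; no scatter (Mie) correction; no
crystallinity or carbonate-to-phosphate indices; the FTIR MINCON edge
fallback above; HCA results depend mildly on the anchor subsample at very
low k; and with n = 6 samples the exact permutation test cannot reach
p < 2/720, so "strictly monotone" is the strongest attainable trend claim.
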