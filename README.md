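# osteospec

Vibrational hyperspectral imaging analysis of human compact bone for
post-mortem interval (PMI) assessment.

Forensic and archaeological bone can be imaged with MIR reflection, ATR and
Raman microscopy: each pixel of the resulting hyperspectral cube is a full
vibrational spectrum whose mineral bands (ν₁–ν₄ PO₄³⁻, B-type carbonate)
and organic bands (amide I/III, C–H stretch and deformation, carbohydrate)
change systematically as bone degrades. `osteospec` implements the complete
analysis chain for such data — and, because spectra of real cadaveric
material are essentially never publicly deposited, a synthetic bone-cube
generator with exact ground truth that stands in for the instrument in
every test:

- **spectral_core** — spectra/cube data model, a self-describing cube
  container format, cropping, masking, Savitzky–Golay smoothing, rubberband
  (convex-hull) baseline correction, vector normalization, Raman despiking;
- **synthetic_data** — osteon-structured tissue templates, pseudo-Voigt
  band libraries per modality, a PMI degradation law
  `A(t) = base·(floor + (1−floor)·e^(−t/τ))` for organic/carbonate bands and
  `A(t) = base·(1 + g·log₁₀(1+t))` for mineral, plus noise and FTIR water
  interference; a default six-sample cohort with PMIs of 1 day, 3, 25, 85,
  760 and 1145 years (four forensic, two archaeological samples);
- **chemimaps** — per-pixel band-area integration ("chemi-maps"), exact
  SNR propagation and 3σ sample-level detection verdicts, false-colour PNGs;
- **ratios** — the mineral content ratio MINCON = ν₄PO₄/amide I and the
  organic-to-mineral ratio OMR = CH-aliphatic/phosphate, with Spearman PMI
  trends and exact permutation p-values (n ≤ 8);
- **mia** — K-means and Ward-HCA segmentation of cube pixels into
  histo-anatomical pseudo-colour maps, scored against the template by
  adjusted Rand index;
- **pca_classify** — ROI selection, PCA per modality and a silhouette-based
  forensic-vs-archaeological separation score;
- **pipeline** — one-seed end-to-end orchestration with a machine-readable
  summary and a Markdown report.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and the limits of what the synthetic validation shows.

## Worked example

```python
from osteospec.synthetic_data import synth_cohort
from osteospec.pipeline import carbonate_detection_verdicts
from osteospec.ratios import cohort_ratio_table, pmi_trend
from osteospec.mia import smallest_k_reaching

cohort = synth_cohort(seed=0)          # six samples x three modalities

# 1. B-type carbonate (756 cm-1) detectability vs PMI
for pmi_years, detected in carbonate_detection_verdicts(cohort):
    print(f"PMI {pmi_years:8.3f} y  carbonate detected: {detected}")

# 2. Ratio trends
table = cohort_ratio_table(cohort)
tr = pmi_trend(table, "mincon", "raman")
print(f"Raman MINCON vs PMI: rho={tr.rho:+.2f}, p={tr.p_value:.5f} ({tr.direction})")

# 3. Histo-anatomical cluster structure of the freshest Raman cube
s = cohort.samples[0]
k, sweep = smallest_k_reaching(s.cubes["raman"], s.template, method="hca", seed=3)
print(f"smallest k with ARI >= 0.7: {k}")
```

prints

```
PMI    0.003 y  carbonate detected: True
PMI    3.000 y  carbonate detected: True
PMI   25.000 y  carbonate detected: False
PMI   85.000 y  carbonate detected: False
PMI  760.000 y  carbonate detected: False
PMI 1145.000 y  carbonate detected: False
Raman MINCON vs PMI: rho=+1.00, p=0.00278 (increasing)
smallest k with ARI >= 0.7: 4
```

Carbonate substituting the apatite lattice is the fastest-decaying marker:
its chemi-map passes the 3σ detection rule only up to the 3-year sample.
MINCON rises strictly with PMI (p = 2/720, the smallest two-sided value an
exact permutation test of six distinct PMIs can produce), and the cluster
sweep resolves the planted four-compartment histo-anatomy (canal, lamellae,
interstitial bone, cement line) at exactly k = 4 — coarser cuts merge the
two large bone compartments.

The full pipeline (maps, ratios, segmentations, PCA score plots, report):

```sh
osteospec run --seed 0 --out-dir run0     # ~1 minute, one CPU
```

`run0/summary.json` then contains, among others, the PCA separation scores
— on the default cohort the Raman channel separates forensic from
archaeological samples best (silhouette 0.53 vs 0.42 ATR / 0.36
reflection), because the modelled adsorbed-water band perturbs the FTIR
amide I region but not the Raman spectra.

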