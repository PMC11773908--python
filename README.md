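# tspoquant

Quantification of TSPO-expressing cells in multiplex immunofluorescence
images of marmoset brain, built around the analysis used to characterise
neuroinflammation in experimental autoimmune encephalomyelitis (EAE).

TSPO (the 18-kDa translocator protein) is the most widely used PET imaging
target for neuroinflammation, yet which cells carry the signal — and how
that changes as lesions age — is unsettled. This package implements the
image-quantification and statistical machinery needed to ask that question
of multiplex immunofluorescence data:

- **Nucleus segmentation with shape classification.** DAPI objects are
  classified as spherical, elliptical, bilobed (two overlapping nuclei) or
  irregular clusters; bilobed and clustered objects are split into member
  nuclei by re-thresholding at higher intensities, with a
  distance-transform watershed fallback.
- **Iba1+ cell masks.** Each microglia/macrophage mask is its nucleus plus
  every contiguous Iba1+ pixel component reachable within a 15-pixel
  Euclidean radius of the nucleus edge (at 0.325 µm/px). Iba1 fragments
  with no nucleus are excluded; pixels contested between cells go to the
  nearest nucleus.
- **Marker calling.** Masks are scanned for TSPO and phenotype markers
  (CD74, CD163, MRP14, Arg1; extensible to NeuN/GLS2/PVA for neurons) with
  strict per-channel thresholds and a minimum above-threshold pixel count.
- **Quantification.** Cell densities per 100,000 pixels, TSPO+ fractions,
  and the full 16-row marker-combination table.
- **Mixed-effects models.** Two bespoke analyses:
  1. a *changepoint model* of the TSPO+/Iba1+ fraction vs. lesion age —
     month-before-sacrifice enters categorically under a
     successive-difference-from-cumulative-average parameterisation, so the
     coefficient for month *t* estimates
     `E[y_t] − mean(E[y_1], …, E[y_{t−1}])`; animal (and optionally
     lesion-within-animal) random intercepts, REML, Bonferroni over the
     month contrasts;
  2. a *weighted neuron model* — per-ROI fractions of TSPO+ neurons with
     fixed effects for disease status and laterality, a random intercept
     per animal, and residual variance ∝ 1/(neurons per ROI).

Because no real images ship with the method, a first-class
**synthetic-tissue module** generates multiplex images and lesion/ROI
tables with known ground truth (nucleus positions and classes, per-cell
marker states, month profiles with a −12.8 percentage-point drop at the
changepoint, binomial counting noise), so every stage can be benchmarked
against truth.

## Worked example

```bash
python examples/lesion_changepoint.py
```

simulates lesions from 20 animals with a 12.8 pp drop in the TSPO+
fraction at month 5 and fits the changepoint model:

```
             term  estimate_pp    se_pp    p_raw  p_bonferroni
month_2_vs_cumavg      -0.3225   0.5069   0.5246        1.0000
month_3_vs_cumavg      -0.1062   0.5667   0.8513        1.0000
month_4_vs_cumavg       0.6342   0.5604   0.2578        1.0000
month_5_vs_cumavg     -12.6494   0.5523   0.0000        0.0000
...
estimated month-5 contrast: -12.65 pp (SE 0.55, Bonferroni p 3.16e-115)
```

The month-5 row is the changepoint contrast: lesions five months old
differ from the running average of months 1–4 by −12.65 pp, recovering the
simulated −12.8 pp drop within its standard error; earlier months are
correctly flat. Other examples cover segmentation
(`simulate_and_segment.py`), per-cell phenotyping
(`phenotype_microglia.py`) and the weighted neuron model
(`neuron_tspo.py`).

A thin CLI exposes the same stages
(`tspoquant simulate-image | segment | phenotype | quantify |
fit-changepoint | fit-neurons`, each with `--seed`/`--out` and a YAML
config for thresholds).

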