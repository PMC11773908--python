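# Methods

This note documents the models, algorithms and design choices behind
tspoquant: what each stage assumes, which tunables matter, what the
synthetic benchmark does and does not establish, and where the genuinely
open design decisions were resolved.

## Image model and segmentation

Images are multi-page 16-bit TIFFs on a shared pixel grid at 0.325 µm/px.
Channel identity is always carried by an explicit page→name map; page
order alone is never trusted, because multiplex panels change across
staining/stripping rounds. Pixel coordinates are 0-based `(y, x)` with
8-connected objects; ROI boxes are half-open. Physical lengths convert to
pixels by rounding down (500 µm → 1538 px), so a stated extent is never
exceeded.

**Binarisation.** The DAPI channel is thresholded by Otsu's method unless
a fixed threshold is configured. A uniformly saturated image is an error
(no threshold exists); a constant background returns no nuclei.

**Shape classification.** Each connected object ≥ `min_area` (default
30 px, the operational meaning of a "visible" nucleus; debris below it is
discarded) is classified from its silhouette:

1. *spherical* — one distance-transform lobe and circularity
   `4πA/P² ≥ c_spherical` (default 0.85);
2. *elliptical* — solidity ≥ 0.90 and eccentricity ≥ `e_min`
   (default 0.85);
3. *bilobed* — exactly two distance-transform lobes;
4. *cluster* — otherwise.

Lobes are h-maxima of the Euclidean distance transform with depth
`max(1.25 px, 0.2 × max EDT)`. The 1.25 px floor suppresses the ≈1 px
quantisation bumps the integer lattice produces along thin diagonal
ridges. The eccentricity cutoff is deliberately high: the union of two
equal disks overlapping end-to-end has moment eccentricity ≈ 0.80–0.85,
so a lower cutoff would absorb bilobed pairs into the ellipse class.
Measured on rasterised shapes, true elongated nuclei (axis ratio ≥ 2.2)
sit at ≥ 0.88. The lobe count additionally gates the spherical class
because rasterised perimeters underestimate, inflating the circularity of
shallow-waisted pairs above 0.85. All cutoffs live in the config.

**Splitting.** Bilobed and cluster objects are split the way overlapping
nuclei are actually separable: their interiors are brighter than the
overlap neck, so the local threshold is raised in steps of 5% of the
object's intensity maximum and the labelling with the most cores (each ≥
half of `min_area`; cores are grown back to full members afterwards) is
kept. The scan stops at 80% of the local maximum — above that the
supra-threshold set is noise-dominated and fragments spuriously. If no
threshold separates the object (e.g. homogeneous intensity), a watershed
on the distance transform seeded at the lobe maxima is the fallback;
if that also fails the parent is returned unsplit and flagged. Member
pixels partition the parent: unclaimed rim pixels join the nearest
member. Because a strongly overlapping pair can pass the ellipse test on
silhouette alone, the intensity-core scan also runs on objects classified
spherical/elliptical; when it finds ≥ 2 cores, the intensity evidence
wins and the object is split. A bilobed parent must yield exactly two
members; surplus members are merged smallest-first into their nearest
neighbour.

Nucleus ids are assigned in raster order of the centroid, making repeated
runs identical.

## Cell masks and marker calls

A microglia/macrophage cell is nucleus-anchored by construction — Iba1
fragments, apoptotic debris and orphan nuclei never form cells. The
candidate region is the set of pixels within Euclidean distance `r_px`
(default 15, a disk — "radius" is read literally, not as a Chebyshev
box) of the nucleus pixel set. Every above-threshold 8-connected Iba1
component intersecting that ring is added to the mask in full; with
`r_px = 0` the ring is empty and masks reduce to bare nuclei. Components
shared between nuclei are then partitioned: each contested pixel goes to
the cell whose nucleus is nearest, ties to the lower nucleus id, so final
masks are disjoint and their areas sum exactly.

A marker is called positive when at least `min_pos_px` (default 5) mask
pixels strictly exceed the per-channel threshold θ_c. The pixel-count
floor resists shot noise; strict inequality fixes boundary behaviour.
Thresholds are never hard-coded: the original analysis chose its TSPO
threshold by manual inspection, so on real data θ_c is user-supplied; on
synthetic data the generator's background/foreground midpoint is the
default. Raising any θ_c can only shrink that marker's positive set
(monotonicity, tested).

Neuron counting reuses the same machinery with NeuN as the mask-growing
channel and TSPO/GLS2/PVA as markers; ROIs with no detected neuron are
flagged and excluded from weighting. This automates a count done manually
in the original workflow — a manually counted CSV with the same columns
drops into the model unchanged.

## Synthetic tissue

The generator is the package's study design: it renders what the
pipeline's assumptions say tissue looks like, with ground truth.

- Nuclei are flat-topped domes, `I(u) = fg·exp(−k·u⁴)` with 25% of peak
  at the true boundary `u = 1`, composed by **maximum** (overlapping
  nuclei do not double their chromatin signal). The quartic profile makes
  the thresholded silhouette track the true boundary; max-blending keeps
  the waist between overlapping nuclei visible. Bilobed pairs sit at 1.6
  radii separation (still overlapping — the sum of radii is 2), clusters
  of k ≥ 3 on a ring.
- Iba1 cytoplasm is an annulus (default 4 px) touching the nucleus
  boundary, guaranteeing contiguity under the 15-px rule; a configurable
  number of detached Iba1 debris blobs, placed beyond scanning reach of
  any nucleus, exercises the exclusion rule.
- Ground-truth cell masks are pre-partitioned by the same nearest-nucleus
  rule the pipeline uses — real cytoplasm is exclusive, and without this
  the per-cell truth of overlapping members would be ill-defined.
- Marker channels render bright over a cell's mask iff the cell's drawn
  state is positive. Default frequencies among Iba1+ cells follow the
  healthy-cortex profile (TSPO 0.765, Arg1 0.221, CD74 0.112, CD163
  0.017, MRP14 5×10⁻⁴). Neurons draw GLS2/PVA states; TSPO appears in
  40.7% of GLS2+ neurons and never in PVA+GLS2− interneurons.
- Degradation: Gaussian blur (σ = 1 px), Poisson shot noise, additive
  Gaussian read noise (σ = 150 counts) — a generic widefield sCMOS model,
  not a claim about any particular camera. Foreground 20,000 counts over
  background 500.

The lesion-table generator draws, per lesion,
`clamp(µ + β_month + β_T·treated + a_i + b_ij, 0, 1)` observed through
`Binomial(n_cells)/n_cells`. Random effects are Gaussian **on the
fraction scale** — the analysis models fractions directly with a linear
model, so the generator matches it; the distributional family of the real
between-animal variation is unknown and this is an explicit assumption.
Clamping events are counted and reported; at the defaults (µ = 0.88,
σ_animal = 0.03, σ_lesion = 0.02, months 1–8 balanced, drop
δ = −12.8 pp from month 5 onward) the clamp rate is zero. The
treated-animal indicator covers the last two of six animals, mirroring a
cohort with two steroid-treated members, with a zero default effect: the
reported treatment estimate in the motivating analysis (23.0 pp,
SEM 21.5) is statistically indistinguishable from zero, and simulating a
23 pp shift on a 0.88 baseline would force clamping.

The neuron-ROI generator uses group means of 0.6% (control) and 12.1%
(EAE), one control and five EAE animals, two ROIs per side, an animal SD
of 0.05 on the fraction scale, and 150 neurons per ROI as a plausible
count for a 500 × 500 µm cortical field.

**What passing the synthetic benchmark shows — and does not.** It shows
the implementation is internally correct: objects the model generates are
recovered, split, phenotyped and modelled back to their known truth. It
does not show the pipeline's accuracy on real tissue, which has chromatin
texture, uneven illumination, autofluorescence, anisotropic cell shapes
and marker gradients none of which are rendered. Residual phenotyping
errors in the benchmark (~1–2% of cells) are almost entirely blur bleed
across the shared boundary of overlapping cells with discordant states —
a few above-threshold pixels leaking over the 5-px positivity floor —
which is also the dominant error mode to expect on real data.

## Mixed models

**Changepoint model.** `fraction ~ month (categorical) + treated` with a
random intercept per animal, REML, via statsmodels MixedLM. Month is
never treated as linear. The categorical coding is built directly: the
design matrix is `D·C⁻¹` where row *t* ≥ 2 of `C` carries `+1` on level
*t* and `−1/(t−1)` on each earlier level (and row 1 picks out the
first-level mean), so fitted coefficients *are* the
successive-difference-from-cumulative-average contrasts, with SEs from
the fit. Bonferroni multiplies the month-contrast p-values by
`levels − 1`. With one observation per lesion the lesion-within-animal
variance is not identifiable separately from the residual, so a single
residual term is fitted; the lesion component is added automatically when
replicate rows per lesion exist. Rows are canonically sorted before
fitting, making results exactly invariant to input order. Optimisation
tries L-BFGS, then Powell, then CG; non-convergence raises with
diagnostics rather than returning estimates. Fixed-effect p-values use a
normal reference (recorded as `df_method="normal"`): the installed
MixedLM provides no Satterthwaite machinery, and with ≈160 lesions the
normal and t references are practically identical.

**Weighted neuron model.** `fraction ~ EAE + side` with a random
intercept per animal and `Var(e_ij) = σ²/w_ij`, `w_ij` = neurons counted
in the ROI. statsmodels MixedLM cannot express residual precision
weights, so this model is fit by a profiled-REML routine written here:
for a given variance ratio λ = σ²_animal/σ², GLS gives β̂ and σ̂² in
closed form and the REML criterion
`(n−p)·log(r'V⁻¹r) + log|V| + log|X'V⁻¹X|` is minimised over λ by a
log-grid plus bounded scalar search, with the λ = 0 boundary checked
explicitly. Only relative weights matter (scale invariance is tested).
lme4's `lmer(…, weights = n_neurons)` fits the identical model and serves
as an independent oracle in the test suite — fixed effects, their SEs and
the animal variance agree to ≤ 10⁻⁵. Inference uses a containment-df t
reference (`df_method="containment-t"`): disease status is an
animal-level contrast, so it is tested on `n_animals − 2` df, laterality
on within-animal df. With six animals a normal reference is visibly
anti-conservative (type-I ≈ 0.11 at nominal 0.05 in null simulations;
the t reference brings it under control).

Fractions are analysed untransformed in both models, matching a linear
model of the fraction itself; a logit transform is deliberately not the
default.

## Numerical and reporting conventions

Densities are reported per 100,000 pixels (with a per-mm² convenience
conversion); fractions are cell-count ratios, never pixel-area ratios;
effects print in percentage points. An empty denominator (no cells in a
subset, no neurons in an ROI) raises or flags — it is never silently
zero. All generators are pure functions of `(params, seed)`; CSV output
is byte-stable for fixed inputs.

## Benchmark problem sizes

The test suite and acceptance script exercise: 20 (tests) / 8 (script)
images of ~300 nuclei at 1024² px for segmentation recovery; 6 / 4 such
images (~1,800 / 1,200 matched cells) for phenotype-state recovery; 100 /
60 replicate simulations of 20 animals × 10 lesions × 1,000 cells for
changepoint recovery and ±2 SE coverage; 1,000 random vectors for the
contrast identity; and balanced zero-variance designs for the
least-squares oracles. These sizes give two-decimal stability of the
reported rates.

## Known limitations

- Silhouette classification is calibrated for roughly convex nuclei in
  the 5–8 px radius range; very elongated or lobulated real nuclei will
  land in the cluster class and be split only if intensity cores exist.
- The 15-px scan includes the nucleus interior in the mask by
  construction; whether the original rule did is not stated anywhere and
  the choice is recorded here.
- TSPO subcellular pattern (perinuclear vesicular vs. diffuse) is out of
  scope; calls are intensity-threshold counts only.
- The changepoint model estimates a drop *given* the changepoint month;
  it does not search for the changepoint location.
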