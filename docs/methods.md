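# Methods

This note documents the models, conventions, and numerical choices behind
`morphoscreen`, and what the synthetic benchmarks do and do not demonstrate.

## Phantom model

Each structure is a radially-parameterized silhouette: a circle of target
projected area perturbed by a low-order random radial Fourier series (modes
2–6, total amplitude = `shape_irregularity`, base radius rescaled so the
analytic area of the perturbed outline equals the target; rendered masks land
within 2% of the requested area for areas ≥ 2000 µm²). Compartments are
nested offsets of the same outline:

* **XEn ring** — an annulus of thickness `xen_ring_thickness` (default
  12 µm) at the silhouette boundary; Gata6-bright, moderately nuclei-bright.
* **Delamination gap** — an annulus of prescribed area at background level
  between the ring's inner boundary and the epiblast, the morphological
  signature of XEn detachment. Gaps are drawn from N(1700, 400²) µm²
  truncated below at 500 µm² for delaminated variants, capped at 55% of the
  ring interior so the Epi remains a real compartment.
* **Epiblast (Epi)** — nuclei-dense disc filling the remaining interior.
* **Cavities** — nuclei-dark, actin-rimmed lumens inside the Epi. The
  terminal XEn/EpiC carries one central pro-amniotic cavity (18% of Epi
  area); multi-cavity variants disperse `cavity_count` smaller lumens
  (area fraction min(0.06, 0.18/k) each) with ≥ 4–5 px tissue walls between
  lumens and to the Epi boundary, falling back to a deterministic ring
  arrangement when rejection sampling cannot place them.

Class geometry: XEn/EpiC = ring + Epi + 1 central cavity; rosette = ring +
Epi + central actin focus, no open cavity; non-polarized Epi = ring + uniform
Epi, 0–k dispersed cavities; EB-like = no ring, scattered Gata6-positive
cells; amorphous XEn = irregular (`shape_irregularity` 0.20) uniformly
Gata6-bright blob. Default areas 7000 / 6500 / 6500 / 5000 / 3500 µm² with
7% CV biological jitter; the control class mixture is (0.72, 0.18, 0.04,
0.04, 0.02) — the dominant 72% XEn/EpiC and 4% non-polarized fractions are
the published control values, the remaining split among rosette/EB/amorphous
is a generator parameter chosen to make the control morphologically rich.
The control delaminated fraction is 16%.

Channels carry class-specific mean levels (nuclei 3000, Gata6 3000, actin
2500, caspase 400 ADU over a background of 100) modulated by a multiplicative
cell-scale granularity field (Gaussian-filtered noise, σ = 2 px, 22%
amplitude) so texture features are informative. The Caspase channel follows a
4-vector of per-radial-bin levels (bin 1 innermost = cavity, bin 4 = XEn),
modeling compartment-localized cell death. Noise is background + shot + read:
pixels are N(I, I/q + σ_r²) with photon scale q = 0.1 counts/ADU and
σ_r = 12 ADU — the Gaussian approximation to Poisson shot noise, exact to
within a fraction of a percent at the ≥ 10-photon counts guaranteed by the
background, and an order of magnitude faster on montage-sized arrays.

Scene defaults: 300 µm microwells on a 1.2× pitch, 15 × 11 grid, 165
structures per well, 0.8 µm/px (20× air-objective scale; the 5000–9000 µm²
areas then span ~90–120 px diameters), single focal plane, one structure per
microwell with ≤ 12% center jitter. Reproducibility: every well draws an
independent RNG stream derived from SHA-256 of (seed, well id), so outputs
are byte-identical for identical (scenario, scene, seed) and independent of
generation order.

**What the phantoms do not emulate:** optical PSF blur, z-projection
artifacts, stitching seams, debris and clumped/overlapping aggregates,
uneven illumination, and the full biological heterogeneity of real structures
(partial rings, graded reporter expression, intermediate morphologies).
Passing recovery benchmarks therefore demonstrates the internal consistency
and statistical machinery of the pipeline — not that the classifier would
reach the same metrics on real microscopy, where class boundaries are far
fuzzier.

## Segmentation

Weighted channel sum (nuclei 0.5 + actin 0.5; the Gata6 channel is excluded
so EB-like/amorphous classes segment identically to ring-bearing ones) →
Gaussian smoothing (3.2 µm) → global Otsu threshold → hole filling →
connected components → equivalent-diameter filter (40–200 µm, bracketing the
observed area range) → optional border exclusion. A degenerate-blank guard
returns an empty object list when Otsu merely split the noise floor
(foreground mean < 1.5× background mean). No declumping/watershed: the
microwell geometry guarantees one aggregate per well; clumps would be
under-segmented (known limitation). Microwell assignment takes the nearest
well center; one object per well is kept (largest pixel count, ties to the
lower label), the rest flagged duplicates.

## Feature conventions

* **Perimeter / form factor** — 4-direction Crofton estimate of the crack
  boundary; the raw 4-connected crack count overestimates circle perimeters
  by ~5% and would bias 4πA/P² to ~0.91 for discs. Values marginally above 1
  can still occur from discretization.
* **Zernike** — magnitudes |A_nm| for n ≤ 9, m ≥ 0, n−m even (30 values) of
  the binary silhouette, unit disc = circumscribed circle at the centroid,
  mask normalized to unit mass: A_nm = (n+1)/π · Σ f·R_nm(ρ)·e^(−imθ).
  Translation-invariant by centering; rotation-invariant within ~1–2%
  discretization residuals.
* **Radial distribution** — normalized distance is the per-object
  distance-to-edge transform scaled to [0, 1] (robust to irregular
  outlines), cut into 4 equal bins, bin 1 innermost. FracAtD is the bin's
  share of total intensity; MeanFrac divides by the bin's pixel fraction.
  RadialCV is the coefficient of variation over the 8 angular wedges about
  the centroid of the **per-wedge mean intensities** (pixel-count
  normalized) within the bin — so a uniform image gives exactly 0 for any
  outline shape; raw wedge sums would conflate geometry with intensity.
  Empty wedges are excluded; zero-intensity objects return flagged NaNs.
* **Texture** — gray-level co-occurrence at offset 3 px averaged over the 4
  standard directions, 8 gray levels quantized over the per-object intensity
  range (image-range quantization would couple an object's texture to its
  neighbors); 13 Haralick statistics with natural logarithms, sum variance
  centered on the sum average (the common software variant), correlation
  NaN-flagged for constant objects.
* **Delamination** — the Gata6 ring is thresholded at background + 0.5 ×
  (95th-percentile signal − background) after 1.5 px smoothing, closed
  (4 µm), and must hug ≥ 50% of the object's outer boundary (this rejects
  amorphous blobs, which have no interior, and chains of scattered
  Gata6-positive EB cells) and enclose ≥ 500 µm². The Epi is the largest
  nuclei-bright component inside the ring's inner contour, hole-filled
  (lumens are part of the Epi outline), thresholded at background + 0.35 ×
  (p95 − background). Background-referenced thresholds are used instead of
  Otsu because a lumen-free interior is unimodal and Otsu would split the
  Epi's own granularity. The 0.35 fraction and 1.5 px smoothing were
  calibrated on the rendering model's blur scale to make the gap estimator
  unbiased: recovered means are within ~±3% of truth for gaps of
  500–2600 µm²; half-max thresholding would shrink the Epi (the p95
  reference overshoots the plateau mean) and inflate small gaps ~20%.
  Delamination area = interior area − Epi area, floored at 0.
* **Cavities** — connected nuclei-dark holes in the Epi component of area
  ≥ 50 µm² (rejects single-pixel noise holes; rendered lumens are ≥ 200 µm²).

## Classifier

Multi-class gentle boosting of decision stumps, the classifier family of
CellProfiler-Analyst-style phenotype scoring. With y(i,k) = ±1 one-vs-rest
indicators and weights w(i,k) initialized uniform, each round searches every
feature and every candidate threshold (midpoints between consecutive sorted
unique values — scale-free and exact on small sets), fits the two-sided
responses a_k, b_k as weighted means of y, picks the split minimizing total
weighted squared error (ties: lower feature index, then lower threshold),
and updates w ← w·exp(−y·h) with renormalization. Because |h| ≤ 1, the
weighted exponential loss is non-increasing every round (tracked in
`loss_history` and asserted in tests). Scoring sums vote vectors; prediction
is arg-max with ties resolved to the earliest class along the developmental
continuum (EB-like → amorphous → non-polarized → rosette → XEn/EpiC), which
is conservative for terminal-phenotype yield. Defaults: 50 rounds (balanced
against the 25–30 exemplars/class training regime), non-finite features
median-imputed from the training set with medians embedded in the serialized
rules so scoring never crashes on flagged values.

Training-set curation mirrors screening practice: the five-class fixtures
draw exemplars from the screened population, so ring-bearing classes include
delaminated variants at the control fraction (16%) — a phenotype keeps its
class label whether or not its XEn layer has detached. The binary
delaminated/attached model is trained on exemplars curated from a rendered
training well (45% delaminated, exact counts, every phenotype represented
among the attached) and measured through the same montage segmentation path
as the screen; training this model on isolated patches instead leaves its
decision boundary under-determined and unstable under the patch/montage
domain shift.

## Screen statistics

Yields are computed per well (Σ = 100%) and summarized as mean ± SD over the
n = 3 replicate wells — never by pooling objects across wells. Area
endpoints are object-level (each dot one XEn/EpiC), yield and
delaminated-yield endpoints well-level.

Dunnett's many-to-one test: one-way-ANOVA pooled variance, two-sided
t-statistics per treatment vs control, adjusted p from the null distribution
of max|T| over treatments with the equal-correlation structure implied by
group sizes, evaluated by Monte Carlo (2×10⁵ draws, seeded; group means
N(0, σ²/nᵢ), pooled variance σ²·χ²_df/df). Monte-Carlo evaluation is
preferred to multivariate-t quadrature because it is transparently
oracle-testable; agreement with a 10⁶-draw independent simulation is within
0.005 and with `scipy.stats.dunnett` within 0.01, and the k = 1 case reduces
to the pooled two-sample t-test. Stars: \* p ≤ 0.05, \*\* p < 0.01,
\*\*\* p < 0.001, \*\*\*\* p < 0.0001.

The compound effect categorizer formalizes the narrative groupings of a
three-dose screen, evaluated in order: *no_effect* (no significant endpoint);
*cytotoxic_morphotoxic* (top-dose terminal yield ≤ 20% with
morphology flags); *morphotoxic* (significant earlier-stage/delamination/
multi-cavity increase or area reduction at viable top-dose yield);
*gradient* (significant, monotone terminal-yield decrease with no
morphology/area change); else *unclassified*. All thresholds (α = 0.05,
20% yield floor, 3 pp monotonicity tolerance) are configurable and reported
alongside the category. Viability (ATP luminescence) tables are normalized
to the same-timepoint control; a condition is *irreversible* when the 120 h
normalized signal fell below both its 72 h value and 0.5, *recovered* at
≥ 0.9.

## Benchmark fixtures and problem sizes

The recovery benchmarks regenerate their inputs at the campaign's study
conditions: 3 replicate wells × 165 structures for yield and
delaminated-yield recovery; 165 structures for each cavity-distribution
fixture (medium-dose retinoic-acid distribution {0: 45%, 1: 28%, 2: 13%,
3: 8%, 4: 6%}; low-dose {0: 52%, 1: 45%, 2: 2%, 3: 1%} — the published
low-dose figures leave ~40% of structures unaccounted, assigned here to the
no-cavity bin); 30 training / 100 held-out structures per class for the
classifier benchmark; 15–40 renders per condition for gap and area recovery.
Recovery fixtures use exact-count (largest-remainder) composition rather
than i.i.d. draws: at n = 165 and p = 0.13 the binomial SE alone is 2.6 pp,
which would swamp a ±3 pp check of the measurement pipeline; i.i.d. sampling
remains the default for scenario simulation and is what the mixture-recovery
property tests exercise. A 288-well × 160-structure campaign is enumerated
in ground-truth-only mode (no rasterization) for bookkeeping checks.

## Known limitations

* Compartment detection assumes the rendering model's contrast ordering
  (bright ring, dark gap, bright Epi); its thresholds are calibrated to this
  model, and real images would need recalibration against manual annotation.
* One aggregate per microwell is assumed end to end.
* The classifier consumes the full feature vector; no feature selection or
  probability calibration is performed.
* Rule-based effect categories inherit the configured thresholds; they are
  an explicit, reproducible formalization, not a learned boundary.
* 2D only: no z-stacks, no optical modeling, no time series.
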