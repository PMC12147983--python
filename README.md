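# morphoscreen

Morphometric developmental-toxicity ("morphotoxicity") screening of
stem-cell-based embryo models cultured in microwell arrays.

Peri-implantation embryo models (XEn/EpiCs — an epithelialized,
Gata6-positive extraembryonic-endoderm ring enclosing a polarized epiblast
with a central pro-amniotic cavity) self-organize by the hundreds in 300 µm
microwells and can be imaged as multi-channel fluorescence montages, one
structure per well. Compounds that disturb morphogenesis shift the population
toward earlier or disorganized phenotypes, detach the XEn layer from the
epiblast (delamination), scatter the single cavity into many, or shrink the
structures — with or without outright cytotoxicity. `morphoscreen` implements
the complete automated read-out chain for such screens, plus a ground-truthed
synthetic phantom generator so every stage can be validated without any
imaging data:

* **`morphoscreen.phantoms`** — renders 16-bit multi-channel montages
  (nuclei / Gata6 reporter / F-actin / cleaved Caspase-3/7) of microwell
  arrays populated with five phenotype classes — XEn/EpiC, XEn/Epi rosette,
  XEn/non-polarized Epi, EB-like, amorphous XEn — including delaminated and
  multi-cavity variants, with a per-structure ground-truth table.
* **`morphoscreen.segmentation`** — one labeled object per occupied
  microwell (weighted channel sum → Gaussian smoothing → Otsu → hole filling
  → size filter).
* **`morphoscreen.features`** — the morphometric families of a
  high-content-screening pipeline: area/size/shape, Zernike moments
  (n ≤ 9, 30 magnitudes), per-channel intensity statistics, radial intensity
  distribution in 4 edge-distance bins with per-bin angular RadialCV, and 13
  Haralick texture statistics; plus compartment measurements — delamination
  area (inner-XEn area − Epi area) and cavity counts.
* **`morphoscreen.boosting`** — fast gentle boosting of regression stumps
  with per-class vote vectors, written from scratch: each round fits one
  stump by weighted least squares against ±1 one-vs-rest indicators,
  `w ← w·exp(−y·h)`; models serialize to human-readable rules text.
* **`morphoscreen.screen`** — per-well phenotype yield% and condition-level
  summaries (mean ± SD over n = 3 replicate wells), class-filtered area
  statistics, one-way ANOVA with Dunnett many-to-one comparisons against the
  control (Monte-Carlo max-|t| null, fixed seed), star annotations
  (\* p ≤ 0.05 … \*\*\*\* p < 0.0001), a rule-based compound effect
  categorizer (gradient / morphotoxic / no-effect / cytotoxic+morphotoxic),
  and ATP-luminescence viability table ingest.

## Worked example

```python
import numpy as np
from morphoscreen import (SceneConfig, DoseGroup, generate_well,
                          segment_montage, assign_microwells)
from morphoscreen.features import measure_objects
from morphoscreen.phantoms import rng_for
from morphoscreen.screen import dunnett_test

# one control well: 5x5 microwell array, 24 structures
scene = SceneConfig(microwell_grid=(5, 5), structures_per_well=24)
montage, truth = generate_well(DoseGroup(dose=0.0), scene,
                               rng_for(1, "demo"), well_id="demo")
objects = assign_microwells(
    segment_montage(montage, pixel_size=scene.pixel_size), scene)
features, compartments = measure_objects(objects, montage, scene.pixel_size)

print(f"segmented {len(objects)} of {len(truth)} structures")
print(f"mean structure area: {features['Area_um2'].mean():.0f} um^2")
ring = compartments[compartments["applicable"]]
print(f"structures with a detected XEn ring: {len(ring)}")
print(f"median delamination area: {ring['delamination_area'].median():.0f} um^2")

# dose-response test on replicate-well XEn/EpiC yields
res = dunnett_test(
    {"control": np.array([72.1, 70.9, 73.3]),
     "1 mM": np.array([63.0, 65.5, 61.8]),
     "2 mM": np.array([49.1, 51.5, 47.3])},
    control="control", seed=1)
print(res.comparisons[["treatment", "mean_diff", "t", "p_adj", "stars"]]
      .to_string(index=False))
```

prints

```
segmented 24 of 24 structures
mean structure area: 6702 um^2
structures with a detected XEn ring: 22
median delamination area: 1 um^2
treatment  mean_diff          t    p_adj stars
     1 mM  -8.666667  -5.982679 0.001725    **
     2 mM -22.800000 -15.739047 0.000005  ****
```

All 24 rendered structures are recovered as one object each; the 22
ring-bearing structures (the control mixture holds ~6% EB-like/amorphous
structures, which have no ring) show an essentially zero detachment gap, as
an attached control should; and both caffeine-like dose groups show a
significant, starred drop in terminal-phenotype yield relative to control.

A full screen (simulate → segment → measure → train → classify → analyze →
report) runs from one YAML config through the CLI:

```bash
morphoscreen all --config examples/demo.yaml --out runs/demo --seed 1
```

producing per-well TIFFs and ground truth, object/feature/prediction tables,
condition summaries with Dunnett tests, effect categories, and figures —
every CSV stamped with a version/seed/config-hash provenance header.

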