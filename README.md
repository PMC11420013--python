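# flowalign

Quantification of cell **elongation** and collective **flow alignment** in
confluent endothelial monolayers, starting from the instance-segmentation
label masks any cell segmenter produces (0 = background, each positive
integer = one cell).

Endothelial cells exposed to laminar shear stress elongate and align with
the flow direction; under static conditions they stay polygonal and
unoriented. `flowalign` turns segmented monolayer images into the two
standard readouts of that phenotype and the rank statistics used to compare
experimental conditions (drug treatments, knockouts, flow vs static). It is
aimed at imaging labs that already run a segmenter (e.g. a Cellpose-style
model) and want a reproducible, tested downstream analysis.

## What it computes

For each cell, from the normalized central second moments of its mask
(pixel-center convention, y-up sign for the mixed moment):

- covariance eigenvalues λ₁ ≥ λ₂ and the **equivalent ellipse** axes
  `major = 4√λ₁`, `minor = 4√λ₂`;
- **elongation factor** `EF = major/minor = √(λ₁/λ₂)` (EF = 1 for isotropic
  cells);
- **orientation** θ = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂), the major-axis angle from
  the horizontal, axial (mod 180°), reported in (−90°, 90°].

Quality control removes partial cells on the image border, oddly shaped
segments with EF > 10, and segmentations smaller than 20% of the largest
cell in the image (strict thresholds, largest cell taken before any
removal).

Alignment is quantified relative to the monolayer itself: each cell's
orientation is re-expressed as its signed axial deviation `d` from the
per-image axial median (which becomes 0); deviations are pooled per
condition, drawn as a radial rose plot (each cell contributes a diameter,
two opposite 10° spokes on 0–360°), and summarised by the **coefficient of
variation** `CV = SD(d + 90°) / mean(d + 90°)`. Fully unaligned monolayers
give CV ≈ 1/√3 ≈ 0.577; perfect alignment drives CV toward 0. Conditions
are compared with a two-tailed Mann-Whitney U test (two groups) or
Kruskal-Wallis with Bonferroni-adjusted Dunn post hoc tests (three or
more).

A synthetic-monolayer generator (anisotropic Voronoi tessellation with
per-cell orientations drawn from an axial von Mises distribution) provides
confluent ground-truth images at any elongation (`stretch`) and alignment
strength (`kappa`), so the whole pipeline is testable without microscopy
data.

## Worked example

```python
import numpy as np
from flowalign import (AnalysisConfig, MonolayerShapeModel, SyntheticSpec,
                       generate_monolayer)

masks = []
for i in range(3):
    static, _ = generate_monolayer(SyntheticSpec(
        image_size=(220, 220), n_cells=64, stretch=1.0, kappa=0.0, rng_seed=i))
    static.condition, static.replicate, static.image_id = "static", f"r{i+1}", f"static_r{i+1}"
    flow, _ = generate_monolayer(SyntheticSpec(
        image_size=(220, 220), n_cells=64, stretch=3.0, kappa=8.0, rng_seed=100 + i))
    flow.condition, flow.replicate, flow.image_id = "flow", f"r{i+1}", f"flow_r{i+1}"
    masks += [static, flow]

results = MonolayerShapeModel(masks, AnalysisConfig()).fit()
print(results.summary())
```

prints

```
Monolayer shape analysis
========================

condition        n cells  EF median  EF mean   EF sd  align CV
flow                 104      2.539    2.560   0.757     0.153
static               108      1.251    1.299   0.228     0.501
```

and then the test line

```
mann-whitney-u-normal: statistic = 10873.0000, p = 5.41e-32 ****
```

Reading it: flow-like monolayers have a median elongation factor of 2.54
versus 1.25 for static-like ones (cells pooled across the three replicate
images after QC), their orientation deviations are tightly concentrated
(CV 0.15, far below the unaligned value ≈ 0.577 that the static condition
approaches at 0.50), and the Mann-Whitney U test rejects equality of the
elongation distributions (four-star tier, p < 0.0001).
`results.save(outdir)` writes the per-cell table, condition summaries,
stats table and radial bins; `results.make_report(outdir)` draws the
violin/box elongation plot and per-condition rose plots.

The same pipeline runs from the shell:

```bash
flowalign simulate --size 220 220 --n-cells 64 --stretch 3 --kappa 8 --seed 1 --out data/
flowalign analyze --manifest manifest.csv --out results/
```

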