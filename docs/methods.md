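# Methods

## Morphometry

Each labelled region is summarised by its equivalent ellipse — the ellipse
sharing the region's normalized central second moments. Moments are taken
over pixel centers with no per-pixel (+1/12) variance correction, the
convention of the dominant region-properties implementations; this makes
small worked examples exactly reproducible (a solid 5-column × 3-row
rectangle has μ₂₀ = 2, μ₀₂ = 2/3, hence major length 4√2 and elongation
factor √3, to machine precision). Image rows point down, so the mixed
moment μ₁₁ is accumulated with y = −row; with that sign, the orientation

θ = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂)

is the angle of the major axis from the horizontal, positive
counter-clockwise when the image is displayed conventionally, and falls in
(−90°, 90°] with no extra wrapping. Axis lengths are 4√λ of the covariance
eigenvalues; elongation factor EF = √(λ₁/λ₂) = major/minor.

Degenerate cases are fixed by convention: a single-pixel cell has EF 1 and
orientation 0; collinear pixels (λ₂ = 0 < λ₁) give minor length 0 and an
EF of +∞, which the aspect filter removes under default settings. An
isotropic region (μ₁₁ = 0, μ₂₀ = μ₀₂) reports orientation 0. Labels are
not required to be connected; a disconnected label is measured as one
region with a logged warning, on the expectation that shape QC removes
pathological cases.

## Quality control

Three filters, with strict inequalities: border contact; EF strictly
greater than 10; area strictly below 20% of the largest cell in the image.
The reference (largest) cell is found **before** any removal and all three
rules are evaluated in one pass over the original set, so the result does
not depend on rule order. One consequence, documented and tested: if the
largest cell itself is removed (e.g. it touches the border), the area
floor still uses its area, and re-running QC on the kept set alone could
in principle remove further cells — QC is applied once per image, not
iterated. On synthetic monolayers the alternative convention (largest cell
after border removal) changes the kept set by well under 2% of cells.

Reason codes are reported with priority border > too_elongated >
too_small; membership in the removed set is priority-independent.

## Alignment statistics

Major-axis orientations are axial (period 180°). The axial difference
wraps into (−90°, 90°], mapping the closed −90° edge to +90°. The axial
median is the data value minimising the summed absolute axial distance to
all orientations, ties broken by the smallest angle in (−90°, 90°] — a
deterministic, exhaustive-search definition that the tests also verify
against an independent brute-force implementation. Deviations are
d_i = wrap(θ_i − median); the median itself maps to 0.

The coefficient of variation is computed on the shifted deviations:

CV = SD(d + 90°) / mean(d + 90°),

with the sample (n−1) standard deviation. Two candidate formulas exist in
principle (CV of |d|, or CV of d + 90°); only the shifted form scales with
the angular spread — it tends to 1/√3 ≈ 0.577 for uniform (unaligned)
orientations and to 0 for perfect alignment — so it is the one that can
reproduce both the unaligned and the strongly aligned regimes, and it is
the package's definition. A finite-sample subtlety the acceptance checks
quantify: centring at the *sample* axial median (which adapts to the data)
biases the uniform-null CV slightly below the asymptotic 1/√3 — the median
CV at n = 100 cells is ≈ 0.545. Applied to i.i.d. uniform deviations
without median-centring, the Monte-Carlo mean CV is within 0.02 of 1/√3.

Radial (rose) histograms bin each deviation as a diameter — one count at
d mod 360° and one at (d + 180°) mod 360° — in 36 bins of 10° by default
(the bin count is configurable and must divide 360). The histogram is
point-symmetric and sums to twice the cell count.

Pooling: the median is always per image ("in that image"); deviations and
elongation factors are pooled per condition across replicate images by
default (matching the n = 3 × 100 convention of pooled per-condition
samples). A `pooling="per-image"` switch instead averages per-image CVs,
since pooled-vs-averaged CV reporting is a genuine ambiguity in practice;
both scopes are exposed and the default is pooled.

## Group statistics

Two conditions: two-tailed Mann-Whitney U, exact enumeration when the
pooled sample has ≤ 12 observations without ties, tie-corrected normal
approximation with continuity correction otherwise. Three or more:
tie-corrected Kruskal-Wallis (χ², k−1 df) with Dunn's pairwise z tests on
pooled mid-ranks, tie-corrected, Bonferroni-adjusted over all pairs by
default (Holm and unadjusted are available) — Bonferroni being the most
common reading of "Dunn's correction". Identical constant samples return
p = 1 rather than an error. Significance is annotated in four tiers
(*, **, ***, **** at 0.05, 0.01, 0.001, 0.0001).

## Synthetic monolayers

The generator emulates the statistical structure the analysis assumes —
a confluent sheet of cells with controllable median elongation and
orientation concentration about a flow axis:

- **Seeding**: a jittered lattice (default jitter 0.35 of the spacing).
  Pure Poisson seeding produces many tiny cells that QC would remove en
  masse; a perfect lattice is degenerate. 0.35 gives a visually and
  statistically plausible cell-size spread.
- **Orientations**: axial von Mises via angle doubling — ψ ~ vM(2μ, κ) on
  the full circle, φ = ψ/2 in (−90°, 90°]. κ = 0 is exactly uniform
  (static-like); κ = 8 is strong alignment (pipeline CV ≈ 0.15).
- **Tessellation**: each pixel joins the seed minimising that seed's own
  anisotropic squared distance (coordinates rotated by φ_i, divided by
  `stretch` along the cell's long axis). A per-seed metric — rather than a
  single global affine stretch — keeps orientation noise controllable per
  cell; a global stretch would force perfect alignment and make CV
  recovery untestable. Every pixel is assigned, so masks are confluent
  with zero background.
- **Connectivity repair**: anisotropic Voronoi cells can be disconnected;
  each label keeps its largest 8-connected component and stray fragments
  are reassigned to the neighbouring label with the longest shared
  boundary, iterated to a fixed point (bounded at 20 sweeps).
- **Rendering** (optional): a membrane channel (inter-label boundary
  blurred by a Gaussian PSF) and a nuclear channel (Gaussian blobs at
  centroids), Poisson photon noise, fully determined by one seed.

One RNG seed drives seeding, jitter and orientations through a single
`numpy` Generator consumed in a fixed order, so identical specs give
identical masks.

What the generator does **not** emulate: curved junction geometry,
segmentation errors (merges/splits), intensity-dependent artefacts,
cell-size gradients, or any monolayer mechanics. Passing recovery tests
therefore demonstrates the *analysis* is correct and sensitive on
tessellation-like data, not that any particular biological dataset would
behave identically. Measured EF is related to, but below, the nominal
`stretch` (neighbours truncate each other), so tests assert monotone
recovery and orientation recovery within 5°, not equality.

Default problem sizes in the tests (≈200–220 px images, 36–64 cells, 10
seeds per parameter point, 200–300 Monte-Carlo replicates for the null CV)
were chosen as the smallest sizes at which the Monte-Carlo bands above are
stable; they run in seconds to a couple of minutes in total.

## Pipeline

`MonolayerShapeModel` (built from masks or a manifest) → `fit()` →
`MonolayerShapeResults`, which holds the per-cell table, per-condition
elongation and alignment summaries, and the rank-test results, and writes
CSV/JSON artefacts plus the standard figures. Images are processed in
sorted (condition, replicate, image) order and outputs carry fixed float
formatting, so identical inputs give byte-identical files and manifest row
order is irrelevant. Images with zero kept cells after QC are excluded
from summaries with a logged warning (their cells remain in the per-cell
table). Group statistics default to elongation factors across conditions;
absolute deviations can be compared instead via `stat_metric`.

## Known limitations

- The CV's finite-sample bias under median-centring (≈ −0.03 at n = 100)
  is inherent to centring at a data-dependent median; comparisons between
  conditions at similar n are unaffected.
- QC is not idempotent by construction (see above); it is defined as a
  single pass per image.
- The +∞ elongation sentinel survives only until QC; callers bypassing QC
  must handle it.
- Rank tests treat cells as independent; replicate-level hierarchical
  inference is out of scope.
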