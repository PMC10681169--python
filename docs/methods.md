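# Methods

## Model and assumptions

The analysis treats a whole-lobe fluorescence image as a marked raster:
every pixel is either deposit signal, tissue, bright peri-airway
autofluorescence, or background (airway lumen / off-lobe space). Deposits
are assumed small relative to the quadrat size, brighter and more
color-saturated than tissue, and resolvable by a per-pixel color rule —
no spot detection or instance segmentation is attempted. Pixels are
assumed square; the microns-per-pixel calibration is a mandatory input and
is never inferred from file metadata, because every micrometre-denominated
parameter (grid cell edge, proximity radius, lumen area floor) converts
through it.

Quadrat counting reduces the point pattern question to count statistics:
under complete spatial randomness (CSR) the count per equal-area cell is
Poisson, so the index of dispersion D = variance/mean equals 1; clustering
inflates the variance (D >> 1) and regular patterns deflate it (D < 1).
The tissue-coverage criterion restores the "equal-area" premise on
perforated tissue by excluding cells that are mostly lumen or background.
Cells with 90–100 % coverage still differ slightly in tissue area, which
biases D upward by roughly lambda x Var(coverage)/mean(coverage) — about
0.01–0.02 at the defaults, well inside the statistical noise of the
estimator (sd ≈ sqrt(2/n_cells)).

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| grid cell edge | 200 | µm | operating point of the 100/200/500 µm sweep; small enough to resolve peri-airway clusters, large enough for mean counts ≥ 2 |
| coverage threshold | 0.90 | — | excludes lumen-dominated cells without discarding the lobe margin |
| signal mode | mask_area | — | pixel count of the deposit mask; robust when fluorophores saturate. `intensity_sum` provided; affinely related on noiseless renderings |
| proximity radius | 200 | µm | the peri-airway band of interest for medium/large airways |
| lumen area floor | 5000 | µm² | separates medium/large airway lumens from alveolar spaces when lumens are derived rather than annotated |
| variance convention | sample (n−1) | — | included cells are a finite sample; switchable, always recorded |
| pattern band δ | 0.2 | — | D within 1±δ labelled `poisson_like`; beyond, `clustered` / `underdispersed` |
| group test | Welch t | — | the compared groups differ in variance by construction, so pooled-variance t is inappropriate; a seeded permutation test is available |

Rounding rule: cell edge in pixels = `round(cell_size_um / mpp)` (floor 1);
grid cells are half-open pixel intervals anchored at a configurable origin,
so every pixel belongs to exactly one cell and totals are conserved exactly
across grid sizes and origins.

## Synthetic scenes: what they emulate, what they do not

The generator produces a rounded-polygon lobe silhouette, non-overlapping
elliptical airway lumens (axis ratio ≤ 2:1, equal-area to the sampled
radius) fully enclosed by tissue, an autofluorescent band of configurable
width hugging each lumen, and deposits rendered as disks (default 1 µm,
i.e. a single pixel at 2 µm/px). Placement regimes:

* `uniform` — CSR over tissue pixels; the null model (counts Poisson,
  peri-airway fraction = geometric tissue-area fraction within range).
* `clustered` — a two-parameter contamination model: with probability
  `cluster_fraction` a deposit lands uniformly on tissue within
  `cluster_range_um` of a lumen, otherwise uniformly on all tissue. The
  ground-truth peri-airway fraction is therefore knowable per scene and
  stored with it. `cluster_range_um` defaults to 200 µm, matching the
  analysis radius; no empirical clustering length-scale is claimed.

Rendering is exact by default (noise_sigma = 0): class palettes are
constant, so masks recovered by the default color model equal the truth
rasters pixel-for-pixel and every downstream test is an honest end-to-end
check of the arithmetic rather than of segmentation difficulty. Gaussian
intensity noise is available (seeded) for robustness checks. What the
scenes do **not** emulate: stitching artefacts and illumination gradients,
optical blur, out-of-focus fluorescence, anisotropic pixels, airway
branching geometry, and deposit aggregation into multi-particle clumps.
Passing tests therefore demonstrate correctness of the quantification
chain on idealised inputs, not segmentation performance on real stitches —
on real data the color thresholds are the user's responsibility and are
serialised with every run for audit.

Determinism: a scene is a pure function of its config (geometry, placement
and noise all derive from `rng_seed` through independent seed streams), so
identical configs give bit-identical scenes and pipeline reruns from an
emitted run config reproduce outputs byte-for-byte.

## Numerical and degenerate-input choices

* D and c_v are undefined at mean 0 and are reported as NaN with a
  `defined=False` flag, never coerced to 0 (a zero would fabricate
  "perfect uniformity" from empty tissue). Zero included cells raises an
  explicit no-analyzable-tissue error.
* Distances are Euclidean, in µm, from the lumen boundary outward via a
  distance transform on the lumen complement (distance measured from the
  boundary, not the centroid, so airway caliber does not masquerade as
  proximity). Proximity accounting is pixel-level, never quadrat-level.
* Annotated airway masks always override hole-derived lumens; derivation
  (fill holes in the tissue mask, keep components above the area floor) is
  a documented heuristic, and off-lobe background can never become a
  lumen because it is not enclosed by tissue.
* The autofluorescence class is subtracted from deposit signal but added
  to tissue coverage; the exclusion is enforced structurally in the mask
  container, not left to callers.
* Morphological cleanup is off by default (images analysed minimally
  processed); a small-object filter is available behind a config flag.

## Validation problem sizes

The test suite validates on 1.2–1.6 mm synthetic fields (600–1600 px at
2 µm/px) and the calibration check on a 7.2 mm field (3600 px), chosen so
the 200 µm / 90 % operating point yields ≥ 500 included cells at mean
count ≈ 4. The acceptance script pools five seeded replicate scenes
(~2 900 included cells) to stabilise the recovered D; the regime-ordering
check averages D over 20 seeds per regime across the full 3 × 4
(grid size × coverage) sweep. The peri-airway recovery check engineers a
clustered scene with ground-truth fraction 0.70 by solving the
contamination fraction from the scene's own geometry, then requires the
pipeline estimate to agree within ±0.03 at n = 1000 deposits.

## Known limitations

* Per-pixel color rules cannot separate touching deposits or correct
  spectral bleed-through; counts are mask areas, not instances.
* Derived lumens require lumens to be fully enclosed holes; lumens cut by
  the lobe boundary are missed unless annotated.
* The grid anchor is the image origin by default; the origin is
  configurable, and for CSR scenes a half-cell shift changes D well within
  its sampling noise, but no anchor optimisation is performed.
* No multiple-testing correction across the grid sweep: the sweep is a
  robustness display, and one headline comparison is reported per
  experiment.
* Formal point-process model fitting (Neyman–Scott, Cox) is out of scope;
  D and c_v are summary statistics, not likelihood-based inferences.
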