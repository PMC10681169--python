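# lungquad

Quadrat-based spatial statistics for whole-lobe lung fluorescence images:
is particle or cell deposition **uniform** across the parenchyma, or
**clustered** (for example around airways)?

The question arises whenever material is delivered to the mouse lung —
aerosol-chamber exposure tends to deposit particles evenly throughout the
parenchyma, while intranasal instillation concentrates them around medium
and large airways — and the downstream immune response follows the
deposition pattern. `lungquad` turns a calibrated whole-lobe fluorescence
stitch (TIFF + microns-per-pixel) into defensible numbers for that
comparison.

## The method

1. **Color masking.** Each pixel is classified in HSV space into three
   classes: fluorescent deposit signal (e.g. red 1 µm microspheres or
   dsRed⁺ neutrophils), tissue, and the bright peri-airway
   autofluorescence that must be *excluded* from deposit signal but still
   counts as tissue.
2. **Quadrat grid.** A square grid (default 200 µm cells) is overlaid and
   each cell gets a deposit signal and a tissue-coverage fraction. Cells
   below a coverage threshold (default 90 %) are excluded so airway lumens
   and off-lobe space cannot masquerade as "empty tissue".
3. **Dispersion statistics.** Over the included cells the package computes
   the index of dispersion

   *D* = σ²∕μ

   (variance-to-mean ratio of per-cell counts) and the coefficient of
   variation *c*ᵥ = σ∕μ. Under complete spatial randomness the counts are
   Poisson and *D* = 1; *D* ≫ 1 indicates clustering; *D* < 1 an unusually
   even pattern. *D* scales with the counts while *c*ᵥ does not, which is
   why the pair together separates genuine clustering from magnitude
   differences.
4. **Peri-airway proximity.** Airway lumens (annotated, or derived as
   area-filtered holes in the tissue mask) anchor a Euclidean distance
   transform; the fraction of total deposit signal within 200 µm of a
   lumen quantifies peri-airway concentration at pixel resolution.
5. **Group comparison.** Per-specimen *D* values or peri-airway fractions
   are compared between exposure groups with Welch's *t*-test (or a seeded
   permutation test).

Because real whole-lobe stitches are rarely shareable, the package ships a
**synthetic scene generator** with exact ground truth (lobe silhouette,
elliptical airway lumens, autofluorescent bands, and seeded particle
placement under a `uniform` or `clustered` regime) against which every
stage is validated.

## Worked example

```python
import lungquad as lq

# a 2.4 x 2.4 mm synthetic field, 4 airways, 600 deposits clustered
# within 200 um of airways with probability 0.9
cfg = lq.SceneConfig(width_px=1200, height_px=1200, microns_per_pixel=2.0,
                     airway_count=4, airway_radius_range_um=(50, 120),
                     particle_count=600, regime="clustered",
                     cluster_fraction=0.9, cluster_range_um=200.0, rng_seed=7)
scene = lq.generate_scene(cfg)

masks = lq.classify(scene.image)                      # three-class masks
table = lq.quantify(masks, scene.image, lq.GridSpec())  # 200 um / 90 % grid
summary = lq.summarize(table)
airways = lq.derive_airways(masks.tissue_mask, microns_per_pixel=2.0)
prox = lq.proximity_fraction(masks.particle_mask, airways, 200.0, 2.0)

print(f"D = {summary.index_of_dispersion:.2f} over {summary.n_cells} cells"
      f" -> {lq.classify_pattern(summary)}")
print(f"peri-airway fraction = {prox.fraction:.3f}"
      f" (ground truth {scene.true_periairway_fraction:.3f})")
```

prints

```
D = 15.59 over 59 cells -> clustered
peri-airway fraction = 0.900 (ground truth 0.900)
```

The dispersion index far above 1 flags the clustered regime, and the
pixel-level proximity fraction recovers the generator's ground truth to
two decimals. Rerunning with `regime="uniform", cluster_fraction=0.0`
yields *D* ≈ 1 and a peri-airway fraction near the geometric tissue-area
fraction within 200 µm of the airways.

A command line mirrors the stages (`lungquad simulate / mask / quantify /
stats / proximity / run`); `lungquad run config.yaml` executes the whole
pipeline and writes per-specimen quadrat CSVs, dispersion and proximity
JSON, group comparisons, a log, and an echoed config that reproduces the
run bit-identically.

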