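"""Quadrat quantification: exact oracles, conservation, and inclusion logic."""

import numpy as np
import pytest

from lungquad import (CalibratedImage, ColorModel, GridSpec, quantify,
                      sweep_grids, summarize)
from lungquad.color_masking import ClassMasks

def _masks_from(particle, tissue):
    particle = np.asarray(particle, dtype=bool)
    tissue = np.asarray(tissue, dtype=bool)
    return ClassMasks(particle_mask=particle, tissue_mask=tissue,
                      autofluor_mask=np.zeros_like(particle), model=ColorModel(),
                      image_shape=particle.shape)


def _img(h, w, mpp=1.0):
    return CalibratedImage(np.zeros((h, w, 3), dtype=np.uint8), mpp,
                           channel_semantics={0: "particle", 1: "tissue", 2: "nuclear"})


def brute_force_table(particle, tissue, size, origin=(0, 0)):
    """Independent per-pixel oracle: dict (row,col) -> (signal, tissue, n)."""
    h, w = particle.shape
    ox, oy = origin
    cells = {}
    for r in range(h):
        for c in range(w):
            key = ((r - oy) // size, (c - ox) // size)
            s, t, n = cells.get(key, (0, 0, 0))
            cells[key] = (s + int(particle[r, c]), t + int(tissue[r, c]), n + 1)
    return cells


def test_400px_image_with_200um_cells_gives_exactly_four_cells():
    img = _img(400, 400, mpp=1.0)
    masks = _masks_from(np.zeros((400, 400)), np.ones((400, 400)))
    table = quantify(masks, img, GridSpec(cell_size_um=200.0))
    assert len(table.data) == 4
    assert (table.data["n_pixels"] == 200 * 200).all()
    assert table.cell_size_px == 200


@pytest.mark.parametrize("origin", [(0, 0), (3, 5)])
def test_quantify_matches_brute_force_per_pixel_oracle(rng, origin):
    particle = rng.random((37, 41)) < 0.1
    tissue = rng.random((37, 41)) < 0.7
    img = _img(37, 41)
    table = quantify(_masks_from(particle, tissue), img,
                     GridSpec(cell_size_um=10.0, coverage_threshold=0.5,
                              origin_px=origin))
    oracle = brute_force_table(particle, tissue, 10, origin)
    assert len(table.data) == len(oracle)
    for row in table.data.itertuples():
        s, t, n = oracle[(row.cell_row, row.cell_col)]
        assert row.signal == s
        assert row.n_pixels == n
        assert row.tissue_fraction == pytest.approx(t / n, rel=1e-12)
        assert row.included == (t / n >= 0.5)


def test_signals_match_ground_truth_center_binning(uniform_scene, uniform_masks):
    """With single-pixel particles, per-cell mask-area signal equals the
    brute-force assignment of true particle centres to cells (up to the
    rare pixel shared by two centres)."""
    s = uniform_scene
    table = quantify(uniform_masks, s.image, GridSpec(cell_size_um=200.0))
    size = table.cell_size_px
    rc = s.particle_pixels
    unique_px = set(map(tuple, rc))
    counts = {}
    for r, c in unique_px:
        key = (r // size, c // size)
        counts[key] = counts.get(key, 0) + 1
    for row in table.data.itertuples():
        assert row.signal == counts.get((row.cell_row, row.cell_col), 0)


def test_signal_conservation_across_grid_sizes_and_origins(uniform_scene, uniform_masks):
    total = float(uniform_masks.particle_mask.sum())
    for spec in (GridSpec(100.0), GridSpec(200.0), GridSpec(500.0),
                 GridSpec(200.0, origin_px=(50, 50)),
                 GridSpec(137.0, origin_px=(13, 91))):
        table = quantify(uniform_masks, uniform_scene.image, spec)
        assert table.total_signal() == total


def test_every_pixel_in_exactly_one_cell(uniform_scene, uniform_masks):
    table = quantify(uniform_masks, uniform_scene.image, GridSpec(200.0, origin_px=(30, 70)))
    h, w = uniform_scene.image.shape
    assert int(table.data["n_pixels"].sum()) == h * w


def test_inclusion_monotone_in_coverage_threshold(uniform_scene, uniform_masks):
    tables = list(sweep_grids(uniform_masks, uniform_scene.image,
                              sizes_um=[200.0], thresholds=[0.5, 0.75, 0.9, 0.98]))
    sets = [set(map(tuple, t.included[["cell_row", "cell_col"]].to_numpy())) for t in tables]
    for lo, hi in zip(sets, sets[1:]):
        assert hi <= lo


def test_sweep_cardinality_and_order(uniform_scene, uniform_masks):
    tables = list(sweep_grids(uniform_masks, uniform_scene.image))
    assert len(tables) == 12
    combos = [(t.grid.cell_size_um, t.grid.coverage_threshold) for t in tables]
    assert combos == [(s, c) for s in (100.0, 200.0, 500.0)
                      for c in (0.50, 0.75, 0.90, 0.98)]


def test_intensity_sum_affinely_related_to_mask_area(uniform_scene, uniform_masks):
    """On a noiseless rendering every particle pixel has the same red
    intensity, so intensity_sum = constant * mask_area cell by cell."""
    area = quantify(uniform_masks, uniform_scene.image, GridSpec(200.0, signal_mode="mask_area"))
    inten = quantify(uniform_masks, uniform_scene.image, GridSpec(200.0, signal_mode="intensity_sum"))
    from lungquad.synthetic_scene import PARTICLE_RGB
    np.testing.assert_allclose(inten.data["signal"].to_numpy(),
                               area.data["signal"].to_numpy() * PARTICLE_RGB[0])


def test_empty_particle_mask_keeps_coverage_driven_inclusion():
    img = _img(40, 40)
    tissue = np.zeros((40, 40), dtype=bool)
    tissue[:, :20] = True  # left half tissue
    table = quantify(_masks_from(np.zeros((40, 40)), tissue), img,
                     GridSpec(cell_size_um=20.0, coverage_threshold=0.9))
    assert (table.data["signal"] == 0).all()
    assert table.data.set_index(["cell_row", "cell_col"])["included"].to_dict() == {
        (0, 0): True, (0, 1): False, (1, 0): True, (1, 1): False}


def test_single_cell_when_cell_exceeds_image():
    img = _img(30, 20)
    table = quantify(_masks_from(np.zeros((30, 20)), np.ones((30, 20))), img,
                     GridSpec(cell_size_um=500.0))
    assert len(table.data) == 1
    assert table.data.iloc[0]["n_pixels"] == 600


def test_cell_size_rounding_rule():
    assert GridSpec(200.0).cell_size_px(0.65) == 308  # round(307.69)
    assert GridSpec(1.0).cell_size_px(10.0) == 1      # floor of 1 px
    assert GridSpec(250.0).cell_size_px(100.0) == 2   # np.rint half-even


def test_shape_mismatch_rejected(uniform_masks):
    img = _img(10, 10)
    with pytest.raises(ValueError):
        quantify(uniform_masks, img, GridSpec(200.0))


def test_csv_round_trip(tmp_path, uniform_scene, uniform_masks):
    import pandas as pd
    table = quantify(uniform_masks, uniform_scene.image, GridSpec(200.0))
    path = table.to_csv(tmp_path / "q.csv")
    back = pd.read_csv(path)
    assert list(back.columns) == ["cell_row", "cell_col", "signal",
                                  "tissue_fraction", "included", "n_pixels"]
    assert len(back) == len(table.data)
    assert (tmp_path / "q.csv.meta.json").exists()
    s = summarize(back.loc[back["included"], "signal"].to_numpy())
    assert s.n_cells == int(table.data["included"].sum())
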