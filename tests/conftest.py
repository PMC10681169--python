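"""Shared synthetic-scene fixtures.

Scenes are generated once per session at sizes small enough to keep the
suite fast but large enough that 200 um quadrats and 200 um proximity bands
are meaningful: all use 2 um/px, so a 1200 px raster is a 2.4 mm field.
"""

import numpy as np
import pytest

from lungquad import (ColorModel, SceneConfig, classify, generate_scene)

MPP = 2.0


def small_uniform_config(seed: int = 7, particles: int = 600) -> SceneConfig:
    return SceneConfig(
        width_px=1200, height_px=1200, microns_per_pixel=MPP,
        airway_count=4, airway_radius_range_um=(50.0, 120.0),
        autofluor_ring_um=40.0, particle_count=particles,
        regime="uniform", rng_seed=seed,
    )


def small_clustered_config(seed: int = 7, particles: int = 600,
                           cluster_fraction: float = 0.9) -> SceneConfig:
    return SceneConfig(
        width_px=1200, height_px=1200, microns_per_pixel=MPP,
        airway_count=4, airway_radius_range_um=(50.0, 120.0),
        autofluor_ring_um=40.0, particle_count=particles,
        regime="clustered", cluster_fraction=cluster_fraction,
        cluster_range_um=200.0, rng_seed=seed,
    )


@pytest.fixture(scope="session")
def uniform_scene():
    return generate_scene(small_uniform_config())


@pytest.fixture(scope="session")
def clustered_scene():
    return generate_scene(small_clustered_config())


@pytest.fixture(scope="session")
def uniform_masks(uniform_scene):
    return classify(uniform_scene.image, ColorModel())


@pytest.fixture(scope="session")
def clustered_masks(clustered_scene):
    return classify(clustered_scene.image, ColorModel())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
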