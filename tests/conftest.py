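import warnings

import numpy as np
import pytest

from cerramap import (assemble_feature_space, default_climatology,
                      default_scene_config, define_seasons,
                      feature_space_config, generate_burn_history,
                      generate_image_collections, generate_landscape,
                      generate_reference_sites, generate_terrain,
                      rasterize_zones)

warnings.filterwarnings("ignore", message=".*reference pixels.*")
warnings.filterwarnings("ignore", message=".*claimed by zones.*")


@pytest.fixture(scope="session")
def climatology():
    return default_climatology()


@pytest.fixture(scope="session")
def small_scene():
    """A 100x100 noise-free scene with all 13 classes, shared across
    tests: (config, labels, terrain, optical, sar, zones, samples)."""
    cfg = default_scene_config(100, 100, sd=0.0, seed=3)
    labels = generate_landscape(cfg)
    terrain = generate_terrain(cfg)
    clim = default_climatology()
    optical, sar = generate_image_collections(labels, cfg, clim)
    zones = generate_reference_sites(labels, 10, seed=3)
    samples = rasterize_zones(zones, labels.grid)
    return dict(config=cfg, labels=labels, terrain=terrain,
                optical=optical, sar=sar, zones=zones, samples=samples,
                climatology=clim)


@pytest.fixture(scope="session")
def small_cube(small_scene):
    seasons = define_seasons(small_scene["climatology"])
    return assemble_feature_space(
        feature_space_config("F6"), small_scene["optical"],
        small_scene["sar"], small_scene["terrain"], seasons)
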