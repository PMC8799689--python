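"""Feature-space construction: hand-computed oracles for every transform."""

import numpy as np
import pytest

from cerramap import (FEATURE_SPACE_IDS, GridSpec, ImageCollection,
                      MonthlyClimatology, RasterGrid, apply_scene_filters,
                      assemble_feature_space, compute_index, db_to_power,
                      define_seasons, feature_space_config, power_to_db,
                      resample_nearest, slope_from_dem, temporal_composite,
                      temporal_variance, texture_layer)
from cerramap.features import FeatureLayerSpec, FeatureSpaceConfig


# ---------------------------------------------------------------------------
# seasons
# ---------------------------------------------------------------------------

def test_default_seasons_are_apr_through_sep(climatology):
    seasons = define_seasons(climatology)
    assert seasons.dry_months == frozenset({4, 5, 6, 7, 8, 9})
    assert seasons.wet_months == frozenset({1, 2, 3, 10, 11, 12})


def test_season_threshold_is_strict():
    clim = MonthlyClimatology((100.0,) * 6 + (99.9,) * 6)
    seasons = define_seasons(clim)
    # exactly 100 mm is NOT below the threshold -> wet
    assert seasons.wet_months == frozenset({1, 2, 3, 4, 5, 6})
    assert seasons.dry_months == frozenset({7, 8, 9, 10, 11, 12})


def test_season_partition_enforced():
    from cerramap.features import SeasonDefinition
    with pytest.raises(ValueError):
        SeasonDefinition(frozenset({1}), frozenset({1, 2}))
    with pytest.raises(ValueError):
        SeasonDefinition(frozenset({1}), frozenset({2}))


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def test_db_power_round_trip():
    assert db_to_power(0.0) == 1.0
    assert np.isclose(db_to_power(-10.0), 0.1)
    assert np.isclose(db_to_power(3.0), 10 ** 0.3)
    x = np.array([-25.0, -12.5, 0.0, 4.0])
    assert np.allclose(power_to_db(db_to_power(x)), x)


def test_index_hand_values():
    b = dict(NIR=np.array([0.4]), Red=np.array([0.1]),
             SWIR1=np.array([0.2]), SWIR2=np.array([0.1]))
    assert np.isclose(compute_index("NDVI", b)[0], 0.3 / 0.5)
    assert np.isclose(compute_index("SAVI", b)[0], 1.5 * 0.3 / 1.0)
    assert np.isclose(compute_index("EVI2", b)[0], 2.5 * 0.3 / 1.64)
    assert np.isclose(compute_index("SWIR21", b)[0], 0.5)
    s = dict(VH=np.array([0.02]), VV=np.array([0.1]))
    assert np.isclose(compute_index("VHVV", s)[0], 0.2)


def test_index_zero_denominator_is_nan():
    b = dict(NIR=np.array([0.0]), Red=np.array([0.0]))
    assert np.isnan(compute_index("NDVI", b)[0])
    with pytest.raises(ValueError):
        compute_index("BOGUS", b)


def test_vhvv_ratio_must_use_linear_power():
    # in dB the "ratio" would be a difference; the linear ratio of
    # -15 dB VH over -8 dB VV is 10**(-0.7)
    vh, vv = -15.0, -8.0
    assert np.isclose(db_to_power(vh) / db_to_power(vv), 10 ** (-0.7))


# ---------------------------------------------------------------------------
# composites / variance
# ---------------------------------------------------------------------------

def _tiny_collection(values_by_month, mask_by_month=None):
    grid = GridSpec(1, 1, 20.0)
    scenes = []
    for m, v in values_by_month.items():
        mask = None
        if mask_by_month and m in mask_by_month:
            mask = np.array([[mask_by_month[m]]])
        scenes.append((m, {"NIR": np.array([[float(v)]])}, mask))
    return ImageCollection(grid, scenes)


def test_median_composite_skips_masked():
    coll = _tiny_collection({1: 1.0, 2: 9.0, 3: 3.0},
                            mask_by_month={2: True})
    out = temporal_composite(coll, "NIR", statistic="median")
    assert out[0, 0] == 2.0  # median of {1, 3}


def test_composite_month_subset_and_mean():
    coll = _tiny_collection({1: 1.0, 2: 2.0, 7: 40.0})
    assert temporal_composite(coll, "NIR", months={1, 2},
                              statistic="mean")[0, 0] == 1.5
    assert temporal_composite(coll, "NIR", months={7})[0, 0] == 40.0
    with pytest.raises(ValueError):
        temporal_composite(coll, "NIR", months={12})


def test_all_masked_pixel_is_nan():
    coll = _tiny_collection({1: 1.0, 2: 2.0},
                            mask_by_month={1: True, 2: True})
    assert np.isnan(temporal_composite(coll, "NIR")[0, 0])


def test_variance_uses_n_minus_one():
    coll = _tiny_collection({1: 0.0, 2: 2.0})
    assert temporal_variance(coll, "NIR")[0, 0] == 2.0  # not 1.0
    solo = _tiny_collection({1: 5.0})
    assert np.isnan(temporal_variance(solo, "NIR")[0, 0])


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------

def test_texture_checkerboard_hand_value():
    grid = GridSpec(9, 9, 20.0)
    vals = np.indices((9, 9)).sum(axis=0) % 2
    sd = texture_layer(RasterGrid(vals.astype(float), grid)).values
    # interior 5x5 window holds 13 of one value and 12 of the other:
    # sample sd = sqrt(25*0.5*... ) computed directly
    vals_window = vals[2:7, 2:7].ravel()
    expect = np.std(vals_window, ddof=1)
    assert np.isclose(sd[4, 4], expect)
    assert np.isclose(sd[4, 4], 0.5099019513592785)


def test_texture_edges_truncated_and_nodata_skipped():
    grid = GridSpec(9, 9, 20.0)
    vals = np.arange(81, dtype=float).reshape(9, 9)
    sd = texture_layer(RasterGrid(vals, grid)).values
    # corner window is 3x3
    assert np.isclose(sd[0, 0], np.std(vals[:3, :3], ddof=1))
    vals2 = vals.copy()
    vals2[4, 4] = np.nan
    sd2 = texture_layer(RasterGrid(vals2, grid)).values
    win = vals[1:6, 1:6].ravel()
    win = win[win != vals[4, 4]]  # the NaN cell drops out of the window
    assert np.isclose(sd2[3, 3], np.std(win, ddof=1))
    assert np.isnan(sd2[4, 4])  # nodata centre stays nodata


def test_texture_window_size_rules():
    grid = GridSpec(5, 5, 20.0)
    r = RasterGrid(np.zeros((5, 5)), grid)
    # 1 ha at 20 m -> 5x5; constant field -> sd 0 everywhere
    assert np.allclose(texture_layer(r).values, 0.0)
    coarse = RasterGrid(np.zeros((5, 5)), GridSpec(5, 5, 200.0))
    with pytest.raises(ValueError):
        texture_layer(coarse)


# ---------------------------------------------------------------------------
# slope
# ---------------------------------------------------------------------------

def test_slope_of_inclined_plane():
    grid = GridSpec(20, 20, 20.0)
    xx = np.arange(20) * 20.0
    z = np.tile(xx * 0.05, (20, 1))  # 5 % grade eastward
    slope = slope_from_dem(RasterGrid(z, grid)).values
    assert np.allclose(slope[1:-1, 1:-1], np.degrees(np.arctan(0.05)))
    assert np.isclose(slope[5, 5], 2.8624052261117456)


def test_slope_rotation_symmetry():
    grid = GridSpec(20, 20, 20.0)
    rng = np.random.default_rng(0)
    z = rng.normal(size=(20, 20)) * 10
    s1 = slope_from_dem(RasterGrid(z, grid)).values
    s2 = slope_from_dem(RasterGrid(np.rot90(z).copy(), grid)).values
    assert np.allclose(np.rot90(s1), s2)
    flat = slope_from_dem(RasterGrid(np.full((20, 20), 500.0), grid)).values
    assert np.allclose(flat, 0.0)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_resample_nearest_oracle():
    src = GridSpec(6, 6, 20.0)
    vals = np.arange(36, dtype=float).reshape(6, 6)
    tgt = GridSpec(4, 4, 30.0)
    out = resample_nearest(vals, src, tgt)
    # target centre (15, -15) falls in source pixel (0, 0); (45, -15) ->
    # col floor(45/20)=2
    assert out[0, 0] == vals[0, 0]
    assert out[0, 1] == vals[0, 2]
    assert out[1, 1] == vals[2, 2]
    # identity resample is exact
    same = resample_nearest(vals, src, src)
    assert np.array_equal(same, vals)


def test_resample_disjoint_extents_raise():
    src = GridSpec(4, 4, 20.0)
    far = GridSpec(4, 4, 20.0, origin_x=10_000.0, origin_y=-10_000.0)
    with pytest.raises(ValueError):
        resample_nearest(np.zeros((4, 4)), src, far)


# ---------------------------------------------------------------------------
# scene filters
# ---------------------------------------------------------------------------

def test_cloud_filter_boundary_and_masking():
    grid = GridSpec(10, 10, 20.0)
    ok = np.zeros((10, 10), bool)
    boundary = np.zeros((10, 10), bool)
    boundary.ravel()[:70] = True  # exactly 70 % -> dropped (>= threshold)
    partial = np.zeros((10, 10), bool)
    partial[0, 0] = True
    coll = ImageCollection(grid, [
        (1, {"NIR": np.full((10, 10), 0.5)}, ok),
        (2, {"NIR": np.full((10, 10), 0.5)}, boundary),
        (3, {"NIR": np.full((10, 10), 0.5)}, partial),
    ])
    kept = apply_scene_filters(coll)
    assert [m for m, _, _ in kept.scenes] == [1, 3]
    assert np.isnan(kept.scenes[1][1]["NIR"][0, 0])
    with pytest.raises(ValueError):
        apply_scene_filters(ImageCollection(
            grid, [(1, {"NIR": np.zeros((10, 10))},
                    np.ones((10, 10), bool))]))


# ---------------------------------------------------------------------------
# configurations F1..F7
# ---------------------------------------------------------------------------

def test_configuration_inventories():
    cfgs = {fid: feature_space_config(fid) for fid in FEATURE_SPACE_IDS}
    names = {fid: {sp.name for sp in c.layers} for fid, c in cfgs.items()}
    # slope everywhere
    assert all("DEM_Slope" in n for n in names.values())
    # F3 has no SAR layers; others with SAR do
    assert not any(sp.source == "S1" for sp in cfgs["F3"].layers)
    assert any(sp.source == "S1" for sp in cfgs["F6"].layers)
    # F2 keeps only annual statistics
    assert all(sp.statistic in ("Ann", "") for sp in cfgs["F2"].layers)
    # F4 = F6 minus the annual-variance layers
    assert names["F6"] - names["F4"] == \
        {n for n in names["F6"] if n.endswith("_Avar")}
    assert names["F4"] <= names["F6"]
    # F5 differs from F6 only by the burn-masking flag
    assert names["F5"] == names["F6"]
    assert cfgs["F5"].burn_masking is False and cfgs["F6"].burn_masking
    # F7 = F6 plus texture layers
    extra = names["F7"] - names["F6"]
    assert extra and all(n.endswith(("_TW", "_TD")) for n in extra)
    # F1: Landsat-like profile, 30 m, no red-edge
    assert cfgs["F1"].pixel_size == 30.0
    assert not any(sp.band.startswith("RE") for sp in cfgs["F1"].layers)
    assert all(c.pixel_size == 20.0 for f, c in cfgs.items() if f != "F1")
    with pytest.raises(ValueError):
        feature_space_config("F9")


def test_config_validation_rules():
    with pytest.raises(ValueError):
        FeatureLayerSpec("S2", "NIR", "TW")  # texture only for indices
    with pytest.raises(ValueError, match="[Ss]lope"):
        FeatureSpaceConfig("X", (FeatureLayerSpec("S2", "NIR", "Ann"),),
                           20.0)
    with pytest.raises(ValueError, match="red-edge"):
        FeatureSpaceConfig("X", (FeatureLayerSpec("L8", "RE1", "Ann"),
                                 FeatureLayerSpec("DEM", "Slope", "")),
                           30.0, optical_profile="L8")


# ---------------------------------------------------------------------------
# full assembly
# ---------------------------------------------------------------------------

def test_assembled_cube_matches_config_and_is_deterministic(small_scene,
                                                            small_cube):
    cfg = feature_space_config("F6")
    assert set(small_cube.layers) == {sp.name for sp in cfg.layers}
    assert small_cube.grid.pixel_size == 20.0
    seasons = define_seasons(small_scene["climatology"])
    again = assemble_feature_space(cfg, small_scene["optical"],
                                   small_scene["sar"],
                                   small_scene["terrain"], seasons)
    for name, layer in small_cube.layers.items():
        a, b = layer.values, again.layers[name].values
        assert np.array_equal(a, b, equal_nan=True), name


def test_assembled_layer_matches_direct_computation(small_scene,
                                                    small_cube):
    seasons = define_seasons(small_scene["climatology"])
    optical = small_scene["optical"]
    direct = temporal_composite(optical, "NIR", seasons.dry_months,
                                "median")
    assert np.allclose(small_cube.layers["S2_NIR_Dry"].values, direct,
                       equal_nan=True)
    # SAR annual mean in dB
    direct_vv = temporal_composite(small_scene["sar"], "VV", None, "mean")
    assert np.allclose(small_cube.layers["S1_VV_Ann"].values, direct_vv,
                       equal_nan=True)


def test_f3_assembly_needs_no_sar(small_scene):
    seasons = define_seasons(small_scene["climatology"])
    cube = assemble_feature_space(feature_space_config("F3"),
                                  small_scene["optical"], None,
                                  small_scene["terrain"], seasons)
    assert not any(n.startswith("S1_") for n in cube.layers)
    with pytest.raises(ValueError):
        assemble_feature_space(feature_space_config("F6"),
                               small_scene["optical"], None,
                               small_scene["terrain"], seasons)


def test_f1_assembly_resamples_to_30m(small_scene):
    seasons = define_seasons(small_scene["climatology"])
    cube = assemble_feature_space(feature_space_config("F1"),
                                  small_scene["optical"],
                                  small_scene["sar"],
                                  small_scene["terrain"], seasons)
    assert cube.grid.pixel_size == 30.0
    src = small_scene["optical"].grid
    # the 30 m grid stays inside the source extent
    assert cube.grid.rows == int(src.rows * 20.0 // 30.0)
    assert cube.grid.rows * 30.0 <= src.rows * 20.0


def test_cube_matrix_shape_and_mask(small_cube):
    X, valid = small_cube.matrix()
    n_pix = small_cube.grid.rows * small_cube.grid.cols
    assert X.shape == (n_pix, len(small_cube.layers))
    assert X.dtype == np.float32
    assert valid.shape == (n_pix,)
    assert np.isfinite(X[valid]).all()
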