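"""Seasonal multi-sensor feature-space construction.

From monthly optical and SAR collections this module derives the per-pixel
feature layers used by the classifier — seasonal (wet/dry/annual)
composites of reflectance bands and vegetation indices, annual variance
(a phenology-magnitude indicator), moving-window texture, SAR backscatter
statistics and terrain slope — and assembles them into one of seven named
feature-space configurations (F1..F7).

Conventions:

* the dry season is the set of months whose climatological precipitation is
  strictly below 100 mm; wet is the complement;
* optical composites are per-pixel medians over unmasked observations, SAR
  composites are per-pixel means; variance uses the n-1 divisor;
* vegetation indices are computed per scene and then composited (the annual
  variance of an index needs per-scene index values, and the same path then
  serves the seasonal statistics for consistency);
* SAR VH/VV statistics are taken in the dB domain; the VH:VV ratio is
  computed per scene in linear sigma-0 power (dB values are converted
  before the ratio) and then averaged;
* everything is resampled (nearest neighbour) to the configuration's target
  pixel size: 20 m for Sentinel-2-like spaces, 30 m for the Landsat-8-like
  space (which has no red-edge bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import GridSpec, RasterGrid, ImageCollection
from .simulate import MonthlyClimatology

__all__ = [
    "SeasonDefinition", "FeatureLayerSpec", "FeatureSpaceConfig",
    "FeatureCube", "define_seasons", "db_to_power", "power_to_db",
    "compute_index", "temporal_composite", "temporal_variance",
    "texture_layer", "slope_from_dem", "resample_nearest",
    "apply_scene_filters", "assemble_feature_space", "feature_space_config",
    "FEATURE_SPACE_IDS",
]

FEATURE_SPACE_IDS = ("F1", "F2", "F3", "F4", "F5", "F6", "F7")

_OPTICAL_BANDS = ("Blue", "Green", "Red", "RE1", "RE2", "RE3", "NIR", "RE4",
                  "SWIR1", "SWIR2")
_INDICES = ("NDVI", "EVI2", "SAVI", "SWIR21")
_L8_MISSING = ("RE1", "RE2", "RE3", "RE4")

#: valid statistics per feature layer
_LAYER_STATS = {
    "Blue": ("Ann", "Wet", "Dry"),
    "Green": ("Ann", "Wet", "Dry"),
    "Red": ("Ann", "Wet", "Dry", "Avar"),
    "RE1": ("Ann", "Wet", "Dry", "Avar"),
    "RE2": ("Ann", "Wet", "Dry", "Avar"),
    "RE3": ("Ann", "Wet", "Dry", "Avar"),
    "NIR": ("Ann", "Wet", "Dry", "Avar"),
    "RE4": ("Ann", "Wet", "Dry", "Avar"),
    "SWIR1": ("Ann", "Wet", "Dry"),
    "SWIR2": ("Ann", "Wet", "Dry"),
    "NDVI": ("Ann", "Wet", "Dry", "Avar", "TW", "TD"),
    "EVI2": ("Ann", "Wet", "Dry", "Avar", "TW", "TD"),
    "SAVI": ("Ann", "Wet", "Dry", "Avar", "TW", "TD"),
    "SWIR21": ("Ann", "Wet", "Dry", "Avar"),
    "VH": ("Ann", "Wet", "Dry", "Avar"),
    "VV": ("Ann", "Wet", "Dry", "Avar"),
    "VHVV": ("Ann", "Wet", "Dry"),
    "Slope": ("",),
}


@dataclass(frozen=True)
class SeasonDefinition:
    """Partition of the 12 calendar months into wet and dry sets."""

    wet_months: frozenset[int]
    dry_months: frozenset[int]

    def __post_init__(self) -> None:
        if self.wet_months & self.dry_months:
            raise ValueError("wet and dry month sets overlap")
        if self.wet_months | self.dry_months != frozenset(range(1, 13)):
            raise ValueError("wet and dry sets must partition months 1..12")


def define_seasons(climatology: MonthlyClimatology,
                   threshold_mm: float = 100.0) -> SeasonDefinition:
    """Dry months are those strictly below the precipitation threshold."""
    dry = frozenset(m + 1 for m, p in enumerate(climatology.precip_mm)
                    if p < threshold_mm)
    wet = frozenset(range(1, 13)) - dry
    return SeasonDefinition(wet, dry)


@dataclass(frozen=True)
class FeatureLayerSpec:
    """One feature layer: source sensor, band/index name, statistic."""

    source: str  # "S2" (optical), "S1" (SAR) or "DEM"
    band: str
    statistic: str  # Ann | Wet | Dry | Avar | TW | TD ("" for Slope)

    def __post_init__(self) -> None:
        if self.band not in _LAYER_STATS:
            raise ValueError(f"unknown feature layer {self.band!r}")
        if self.statistic not in _LAYER_STATS[self.band]:
            raise ValueError(
                f"statistic {self.statistic!r} not valid for {self.band}")

    @property
    def name(self) -> str:
        if self.band == "Slope":
            return "DEM_Slope"
        return f"{self.source}_{self.band}_{self.statistic}"


@dataclass(frozen=True)
class FeatureSpaceConfig:
    """One of the seven feature-space configurations.

    ``optical_profile`` is "S2" (10 bands, 20 m) or "L8" (no red-edge
    bands, 30 m); ``burn_masking`` records whether burned reference zones
    are excluded when this space is classified (off only for F5).
    """

    identifier: str
    layers: tuple[FeatureLayerSpec, ...]
    pixel_size: float
    optical_profile: str = "S2"
    burn_masking: bool = True

    def __post_init__(self) -> None:
        names = [sp.name for sp in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layers in feature space")
        if "DEM_Slope" not in names:
            raise ValueError("slope must be present in every feature space")
        if self.optical_profile == "L8":
            bad = [sp.band for sp in self.layers if sp.band in _L8_MISSING]
            if bad:
                raise ValueError(
                    f"L8 profile has no red-edge bands: {sorted(set(bad))}")


def _optical_specs(profile: str, stats: tuple[str, ...],
                   texture: bool) -> list[FeatureLayerSpec]:
    src = "L8" if profile == "L8" else "S2"
    specs = []
    for band in _OPTICAL_BANDS + _INDICES:
        if profile == "L8" and band in _L8_MISSING:
            continue
        for st in _LAYER_STATS[band]:
            if st in ("TW", "TD"):
                if texture and st in stats:
                    specs.append(FeatureLayerSpec(src, band, st))
            elif st in stats:
                specs.append(FeatureLayerSpec(src, band, st))
    return specs


def _sar_specs(stats: tuple[str, ...]) -> list[FeatureLayerSpec]:
    return [FeatureLayerSpec("S1", band, st)
            for band in ("VH", "VV", "VHVV")
            for st in _LAYER_STATS[band] if st in stats]


def feature_space_config(identifier: str) -> FeatureSpaceConfig:
    """Built-in layer inventories for F1..F7.

    F6 is the reference space: seasonal + annual + annual-variance optical
    (S2) and SAR layers, plus slope. F1 swaps in the Landsat-8-like
    profile at 30 m; F2 keeps only annual statistics; F3 drops SAR; F4
    drops the annual-variance layers; F5 equals F6 but with burned-zone
    masking switched off; F7 adds wet/dry texture layers.
    """
    seasonal = ("Ann", "Wet", "Dry", "Avar")
    if identifier == "F1":
        layers = _optical_specs("L8", seasonal, False) + _sar_specs(seasonal)
        return _finish("F1", layers, 30.0, "L8", True)
    if identifier == "F2":
        layers = _optical_specs("S2", ("Ann",), False) + _sar_specs(("Ann",))
        return _finish("F2", layers, 20.0, "S2", True)
    if identifier == "F3":
        layers = _optical_specs("S2", seasonal, False)
        return _finish("F3", layers, 20.0, "S2", True)
    if identifier == "F4":
        nv = ("Ann", "Wet", "Dry")
        layers = _optical_specs("S2", nv, False) + _sar_specs(nv)
        return _finish("F4", layers, 20.0, "S2", True)
    if identifier in ("F5", "F6"):
        layers = _optical_specs("S2", seasonal, False) + _sar_specs(seasonal)
        return _finish(identifier, layers, 20.0, "S2", identifier == "F6")
    if identifier == "F7":
        layers = _optical_specs("S2", seasonal + ("TW", "TD"), True) \
            + _sar_specs(seasonal)
        return _finish("F7", layers, 20.0, "S2", True)
    raise ValueError(f"unknown feature space id {identifier!r}")


def _finish(fid, layers, px, profile, masking):
    layers = tuple(layers) + (FeatureLayerSpec("DEM", "Slope", ""),)
    return FeatureSpaceConfig(fid, layers, px, profile, masking)


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def db_to_power(x_db):
    """dB -> linear sigma-0 power: 10^(x/10); NaN propagates."""
    return np.power(10.0, np.asarray(x_db, dtype=float) / 10.0)


def power_to_db(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 10.0 * np.log10(x)


def compute_index(name: str, bands: dict[str, np.ndarray]) -> np.ndarray:
    """Vegetation index / band ratio from same-grid band arrays.

    NDVI = (NIR-Red)/(NIR+Red); EVI2 = 2.5(NIR-Red)/(NIR+2.4 Red+1);
    SAVI = 1.5(NIR-Red)/(NIR+Red+0.5); SWIR21 = SWIR2/SWIR1;
    VHVV = sigma0_VH / sigma0_VV (inputs already linear power).
    Output is NaN wherever an input is NaN or a denominator is zero.
    """
    def _ratio(num, den):
        num = np.asarray(num, float)
        den = np.asarray(den, float)
        out = np.full(np.broadcast(num, den).shape, np.nan)
        ok = np.isfinite(num) & np.isfinite(den) & (den != 0)
        out[ok] = num[ok] / den[ok]
        return out

    if name == "NDVI":
        return _ratio(bands["NIR"] - bands["Red"],
                      bands["NIR"] + bands["Red"])
    if name == "EVI2":
        return _ratio(2.5 * (bands["NIR"] - bands["Red"]),
                      bands["NIR"] + 2.4 * bands["Red"] + 1.0)
    if name == "SAVI":
        return _ratio(1.5 * (bands["NIR"] - bands["Red"]),
                      bands["NIR"] + bands["Red"] + 0.5)
    if name == "SWIR21":
        return _ratio(bands["SWIR2"], bands["SWIR1"])
    if name == "VHVV":
        return _ratio(bands["VH"], bands["VV"])
    raise ValueError(f"unknown index {name!r}")


def _monthly_stack(collection: ImageCollection, band: str,
                   months=None) -> np.ndarray:
    """(n_scenes, rows, cols) stack with cloud-masked pixels set to NaN."""
    months = None if months is None else set(months)
    layers = []
    for month, bands, mask in collection.scenes:
        if months is not None and month not in months:
            continue
        arr = np.asarray(bands[band], dtype=float).copy()
        if mask is not None:
            arr[mask] = np.nan
        layers.append(arr)
    if not layers:
        raise ValueError(f"no scenes selected for band {band!r}")
    return np.stack(layers)


def temporal_composite(collection: ImageCollection, band: str,
                       months=None, statistic: str = "median"
                       ) -> np.ndarray:
    """Per-pixel median/mean over unmasked observations in the month set;
    pixels with zero unmasked observations come out NaN."""
    stack = _monthly_stack(collection, band, months)
    fn = {"median": np.nanmedian, "mean": np.nanmean}[statistic]
    with np.errstate(invalid="ignore"), _no_allnan_warning():
        return fn(stack, axis=0)


def temporal_variance(collection: ImageCollection, band: str,
                      months=None) -> np.ndarray:
    """Per-pixel unbiased sample variance (n-1 divisor) over unmasked
    observations; NaN where fewer than 2 observations are available."""
    stack = _monthly_stack(collection, band, months)
    n = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"), _no_allnan_warning():
        var = np.nanvar(stack, axis=0, ddof=1)
    var[n < 2] = np.nan
    return var


class _no_allnan_warning:
    def __enter__(self):
        import warnings
        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        import warnings as w
        w.filterwarnings("ignore", message=".*[Aa]ll-NaN.*")
        w.filterwarnings("ignore", message=".*[Dd]egrees of freedom.*")
        w.filterwarnings("ignore", message=".*[Mm]ean of empty slice.*")
        return self

    def __exit__(self, *a):
        return self._cm.__exit__(*a)


def texture_layer(raster: RasterGrid,
                  window_area_m2: float = 10_000.0) -> RasterGrid:
    """Standard deviation of valid neighbours in a centred square moving
    window of ~the requested area (1 ha at 20 m -> 5x5), truncated at grid
    edges; n-1 divisor."""
    px = raster.grid.pixel_size
    size = int(round(np.sqrt(window_area_m2) / px))
    if size % 2 == 0:
        size += 1
    if size < 3:
        raise ValueError(
            f"window of {window_area_m2} m^2 at {px} m pixels collapses "
            "below 3x3")
    vals = raster.values
    finite = np.isfinite(vals)
    v0 = np.where(finite, vals, 0.0)
    from scipy import ndimage
    ones = np.ones((size, size))
    count = ndimage.correlate(finite.astype(float), ones, mode="constant")
    s1 = ndimage.correlate(v0, ones, mode="constant")
    s2 = ndimage.correlate(v0 ** 2, ones, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / count
        var = (s2 - count * mean ** 2) / (count - 1)
    var = np.clip(var, 0.0, None)
    sd = np.sqrt(var)
    sd[count < 2] = np.nan
    sd[~finite] = np.nan
    return raster.with_values(sd, name=f"{raster.name}_texture")


def slope_from_dem(elevation: RasterGrid) -> RasterGrid:
    """Terrain slope in degrees from a 3x3 Horn finite-difference gradient;
    edge cells use replicated (truncated) neighbourhoods."""
    z = np.pad(elevation.values, 1, mode="edge")
    px = elevation.grid.pixel_size
    dzdx = ((z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
            - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])) / (8 * px)
    dzdy = ((z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
            - (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])) / (8 * px)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return RasterGrid(slope, elevation.grid, name="DEM_Slope")


def resample_nearest(values: np.ndarray, source: GridSpec,
                     target: GridSpec) -> np.ndarray:
    """Each target pixel takes the source pixel containing its centre;
    centres outside the source extent come out NaN."""
    tx = target.origin_x + (np.arange(target.cols) + 0.5) * target.pixel_size
    ty = target.origin_y - (np.arange(target.rows) + 0.5) * target.pixel_size
    col = np.floor((tx - source.origin_x) / source.pixel_size).astype(int)
    row = np.floor((source.origin_y - ty) / source.pixel_size).astype(int)
    ok_c = (col >= 0) & (col < source.cols)
    ok_r = (row >= 0) & (row < source.rows)
    if not ok_c.any() or not ok_r.any():
        raise ValueError("source and target extents are disjoint")
    out = np.full(target.shape, np.nan)
    rr, cc = np.meshgrid(row.clip(0, source.rows - 1),
                         col.clip(0, source.cols - 1), indexing="ij")
    out[:] = np.asarray(values, float)[rr, cc]
    out[~ok_r, :] = np.nan
    out[:, ~ok_c] = np.nan
    return out


def apply_scene_filters(collection: ImageCollection,
                        max_cloud_fraction: float = 0.7) -> ImageCollection:
    """Drop optical scenes whose cloud fraction is >= the threshold and
    apply the cloud mask (as NaN) to retained scenes."""
    kept = []
    for month, bands, mask in collection.scenes:
        if mask is not None and mask.mean() >= max_cloud_fraction:
            continue
        if mask is not None and mask.any():
            bands = {b: np.where(mask, np.nan, np.asarray(a, float))
                     for b, a in bands.items()}
            mask = None  # mask already burnt into the values
        kept.append((month, bands, mask))
    if not kept:
        raise ValueError("no usable imagery: every scene exceeded the "
                         "cloud-cover threshold")
    return ImageCollection(collection.grid, kept)


# ---------------------------------------------------------------------------
# cube assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureCube:
    """Named stack of aligned feature layers for one configuration."""

    config: FeatureSpaceConfig
    grid: GridSpec
    layers: dict[str, RasterGrid]
    season: SeasonDefinition
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, lyr in self.layers.items():
            if lyr.grid.shape != self.grid.shape:
                raise ValueError(f"layer {name} misaligned with cube grid")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows*cols, n_layers) float32 matrix + boolean all-valid mask."""
        stack = np.stack([self.layers[n].values for n in self.layer_names])
        X = stack.reshape(len(self.layers), -1).T.astype(np.float32)
        valid = np.isfinite(X).all(axis=1)
        return X, valid

    def rowcol_from_xy(self, x, y):
        return self.grid.xy_to_rowcol(x, y)


def _target_grid(source: GridSpec, pixel_size: float) -> GridSpec:
    if pixel_size == source.pixel_size:
        return source
    rows = int(source.rows * source.pixel_size // pixel_size)
    cols = int(source.cols * source.pixel_size // pixel_size)
    return GridSpec(max(rows, 1), max(cols, 1), pixel_size,
                    source.origin_x, source.origin_y)


def assemble_feature_space(config: FeatureSpaceConfig,
                           optical: ImageCollection,
                           sar: ImageCollection | None,
                           dem: RasterGrid,
                           seasons: SeasonDefinition,
                           max_cloud_fraction: float = 0.7) -> FeatureCube:
    """Build the full feature cube for one configuration.

    Filters cloudy optical scenes, computes per-scene indices, composites
    per season (median for optical, mean for SAR), derives annual variance
    and texture where configured, and resamples everything to the target
    grid.
    """
    needs_sar = any(sp.source == "S1" for sp in config.layers)
    if needs_sar and sar is None:
        raise ValueError(f"{config.identifier} requires SAR imagery")
    optical = apply_scene_filters(optical, max_cloud_fraction)

    # augment optical scenes with per-scene index layers
    opt_scenes = []
    for month, bands, mask in optical.scenes:
        bands = dict(bands)
        for idx in _INDICES:
            bands[idx] = compute_index(idx, bands)
        opt_scenes.append((month, bands, mask))
    optical = ImageCollection(optical.grid, opt_scenes)

    sar_aug = None
    if needs_sar:
        sar_scenes = []
        for month, bands, mask in sar.scenes:
            bands = dict(bands)
            lin = {p: db_to_power(bands[p]) for p in ("VH", "VV")}
            bands["VHVV"] = compute_index("VHVV", lin)
            sar_scenes.append((month, bands, mask))
        sar_aug = ImageCollection(sar.grid, sar_scenes)

    target = _target_grid(optical.grid, config.pixel_size)
    month_sets = {"Ann": None, "Wet": seasons.wet_months,
                  "Dry": seasons.dry_months}
    layers: dict[str, RasterGrid] = {}

    # cache of native-grid composites for texture sources
    composite_cache: dict[tuple[str, str], np.ndarray] = {}

    def _native(spec: FeatureLayerSpec) -> np.ndarray:
        if spec.source in ("S2", "L8"):
            coll, stat = optical, "median"
        else:
            coll, stat = sar_aug, "mean"
        if spec.statistic == "Avar":
            return temporal_variance(coll, spec.band)
        if spec.statistic in ("Ann", "Wet", "Dry"):
            key = (spec.source, f"{spec.band}_{spec.statistic}")
            if key not in composite_cache:
                composite_cache[key] = temporal_composite(
                    coll, spec.band, month_sets[spec.statistic], stat)
            return composite_cache[key]
        if spec.statistic in ("TW", "TD"):
            season = "Wet" if spec.statistic == "TW" else "Dry"
            key = (spec.source, f"{spec.band}_{season}")
            if key not in composite_cache:
                composite_cache[key] = temporal_composite(
                    coll, spec.band, month_sets[season], stat)
            base = RasterGrid(composite_cache[key], coll.grid,
                              name=spec.band)
            return texture_layer(base).values
        raise ValueError(spec.statistic)

    for spec in config.layers:
        if spec.band == "Slope":
            native = slope_from_dem(dem)
            vals = resample_nearest(native.values, dem.grid, target) \
                if dem.grid != target else native.values
        else:
            if config.optical_profile == "L8" and spec.band in _L8_MISSING:
                raise ValueError(
                    f"layer {spec.band} unavailable for the L8 profile")
            src_grid = optical.grid if spec.source in ("S2", "L8") \
                else sar_aug.grid
            arr = _native(spec)
            vals = resample_nearest(arr, src_grid, target) \
                if src_grid != target else arr
        layers[spec.name] = RasterGrid(vals, target, name=spec.name)

    return FeatureCube(config, target, layers, seasons,
                       provenance={"config": config.identifier,
                                   "n_optical_scenes": len(optical.scenes)})
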