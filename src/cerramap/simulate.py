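"""Synthetic Cerrado-like scenes: landscape, imagery, burns, terrain, sites.

The generators emulate the statistical structure the mapping pipeline
assumes, so every downstream stage is testable without satellite downloads:

* a 13-class label mosaic (8 native physiognomies in 3 formations + 5 other
  covers) with spatially coherent upland patches, riparian corridors
  (gallery forest, wet grassland) along synthetic drainage lines, vereda
  palm stands embedded in the wet-grassland corridors, and
  rupestrian classes biased onto high-slope terrain;
* one optical (10-band, Sentinel-2-like) and one SAR (VH/VV, dB) image per
  month, with class- and season-specific mean signatures plus Gaussian
  noise, random cloud blobs on the optical scenes, and a post-burn "char"
  signature for recently burned pixels;
* monthly burned-area masks with contiguous scars concentrated in the late
  dry / early wet season;
* a smooth random elevation surface;
* pure-class reference zones placed strictly inside patches.

All generators are pure functions of (config, seed): independent seed
streams are derived per generator, so e.g. the terrain paired with a
landscape is reproducible on its own.

The default signatures are plausible but invented reflectance/backscatter
values — they are NOT field measurements of Cerrado vegetation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, box

from .raster import GridSpec, RasterGrid, ImageCollection
from .reference import ReferenceZone
from .scheme import ClassScheme, DEFAULT_SCHEME

__all__ = [
    "OPTICAL_BANDS", "SAR_BANDS", "MonthlyClimatology", "SceneConfig",
    "LabelGrid", "BurnHistory", "default_climatology",
    "default_scene_config", "phenology_scene_config", "generate_terrain",
    "generate_landscape", "generate_burn_history",
    "generate_image_collections", "generate_reference_sites",
]

OPTICAL_BANDS = ("Blue", "Green", "Red", "RE1", "RE2", "RE3", "NIR", "RE4",
                 "SWIR1", "SWIR2")
SAR_BANDS = ("VH", "VV")

# seed-stream indices (SeedSequence spawn keys) per generator
_STREAM = {"terrain": 0, "landscape": 1, "imagery": 2, "clouds": 3,
           "burns": 4, "sites": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(_STREAM[stream],)))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonthlyClimatology:
    """12 monthly mean total precipitation values (mm), Jan..Dec, plus an
    optional temperature series (deg C)."""

    precip_mm: tuple[float, ...]
    temp_c: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.precip_mm) != 12:
            raise ValueError("exactly 12 monthly precipitation values needed")
        if any(p < 0 for p in self.precip_mm):
            raise ValueError("precipitation must be >= 0")
        if self.temp_c is not None and len(self.temp_c) != 12:
            raise ValueError("exactly 12 monthly temperature values needed")


def default_climatology() -> MonthlyClimatology:
    """Central-Cerrado-like seasonality: ~1400 mm/yr, ~130 mm of it falling
    April-September, each of those months below 100 mm."""
    return MonthlyClimatology(
        precip_mm=(245.0, 200.0, 200.0, 45.0, 15.0, 6.0,
                   5.0, 12.0, 45.0, 140.0, 230.0, 250.0),
        temp_c=(23.0, 23.2, 23.0, 22.5, 21.0, 19.8,
                19.5, 21.5, 23.5, 23.8, 23.0, 22.8))


@dataclass(frozen=True)
class SceneConfig:
    """Everything needed to synthesise one study scene.

    ``optical_signatures[cls][band] = (wet_mean, dry_mean, sd)`` with
    reflectance in [0, 1]; ``sar_signatures[cls][pol] = (wet_dB, dry_dB)``
    with a shared ``sar_sd`` (dB). ``class_fractions`` may sum to < 1; the
    remainder is non-vegetated (NV).
    """

    rows: int
    cols: int
    pixel_size: float = 20.0
    n_months: int = 12
    class_fractions: dict[str, float] = field(default_factory=dict)
    optical_signatures: dict[str, dict[str, tuple[float, float, float]]] = \
        field(default_factory=dict)
    sar_signatures: dict[str, dict[str, tuple[float, float]]] = \
        field(default_factory=dict)
    sar_sd: float = 0.4
    cloud_fraction: float = 0.0
    burn_fraction: float = 0.0
    relief_amplitude: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be > 0")
        fr = self.class_fractions
        if any(f < 0 for f in fr.values()):
            raise ValueError("class fractions must be >= 0")
        if sum(fr.values()) > 1.0 + 1e-9:
            raise ValueError("class fractions must sum to <= 1")
        for cls, sig in self.optical_signatures.items():
            for band, (w, d, sd) in sig.items():
                if sd < 0:
                    raise ValueError(f"negative sd for {cls}/{band}")
        if not (0.0 <= self.cloud_fraction <= 1.0):
            raise ValueError("cloud fraction must be in [0, 1]")
        if not (0.0 <= self.burn_fraction <= 1.0):
            raise ValueError("burn fraction must be in [0, 1]")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.rows, self.cols, self.pixel_size)


@dataclass
class LabelGrid:
    """Ground-truth class codes on a grid."""

    values: np.ndarray  # int codes
    grid: GridSpec
    scheme: ClassScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.shape != self.grid.shape:
            raise ValueError("label shape does not match grid")

    def mask_of(self, cls: str) -> np.ndarray:
        return self.values == self.scheme.code_of[cls]

    def fraction_of(self, cls: str) -> float:
        return float(self.mask_of(cls).mean())


@dataclass
class BurnHistory:
    """Monthly boolean burn masks plus per-scar (month, area m^2) records."""

    masks: list[np.ndarray]
    scars: list[tuple[int, float]]
    grid: GridSpec

    @property
    def burned_any(self) -> np.ndarray:
        return np.any(np.stack(self.masks), axis=0) if self.masks else \
            np.zeros(self.grid.shape, bool)


# ---------------------------------------------------------------------------
# default spectral / backscatter signatures (invented, plausible values)
# ---------------------------------------------------------------------------

def _spectrum(blue, green, red, nir, swir1, swir2):
    """Fill the 4 red-edge bands by ramping from red to NIR."""
    s = {"Blue": blue, "Green": green, "Red": red, "NIR": nir,
         "SWIR1": swir1, "SWIR2": swir2}
    for i, b in enumerate(("RE1", "RE2", "RE3"), start=1):
        s[b] = red + (nir - red) * i / 4.0
    s["RE4"] = nir + 0.01
    return s

# per class: wet-season and dry-season anchor spectra
_WET = {
    "CLU":  _spectrum(.030, .060, .050, .380, .220, .120),
    "CS":   _spectrum(.035, .065, .060, .350, .260, .160),
    "CAMR": _spectrum(.050, .080, .090, .280, .300, .200),
    "CSS":  _spectrum(.030, .055, .050, .340, .240, .140),
    "CERR": _spectrum(.045, .070, .075, .300, .290, .190),
    "V":    _spectrum(.025, .050, .040, .420, .200, .090),
    "C":    _spectrum(.022, .045, .035, .400, .190, .100),
    "MG":   _spectrum(.018, .040, .030, .450, .160, .070),
    "PAST": _spectrum(.032, .070, .050, .460, .230, .130),
    "PF":   _spectrum(.020, .042, .032, .430, .150, .075),
    "A":    _spectrum(.030, .060, .040, .500, .210, .110),
    "W":    _spectrum(.040, .050, .030, .020, .010, .008),
    "NV":   _spectrum(.090, .140, .200, .240, .380, .320),
}
_DRY = {
    "CLU":  _spectrum(.032, .060, .070, .300, .250, .150),
    "CS":   _spectrum(.045, .080, .140, .220, .310, .230),
    "CAMR": _spectrum(.055, .090, .150, .200, .340, .250),
    "CSS":  _spectrum(.035, .060, .090, .270, .270, .170),
    "CERR": _spectrum(.050, .075, .110, .240, .310, .220),
    "V":    _spectrum(.026, .050, .045, .380, .210, .100),
    "C":    _spectrum(.024, .046, .045, .360, .210, .120),
    "MG":   _spectrum(.018, .040, .032, .440, .165, .075),
    "PAST": _spectrum(.040, .075, .130, .250, .320, .240),
    "PF":   _spectrum(.021, .043, .035, .410, .160, .082),
    "A":    _spectrum(.070, .110, .180, .250, .350, .280),
    "W":    _spectrum(.040, .050, .030, .020, .010, .008),
    "NV":   _spectrum(.090, .140, .200, .240, .380, .320),
}
# per class: (VH wet, VH dry), (VV wet, VV dry) backscatter in dB
_SAR = {
    "CLU":  {"VH": (-18.0, -20.0), "VV": (-9.0, -12.0)},
    "CS":   {"VH": (-18.5, -21.0), "VV": (-11.0, -13.5)},
    "CAMR": {"VH": (-16.0, -16.5), "VV": (-10.0, -10.5)},
    "CSS":  {"VH": (-14.0, -15.0), "VV": (-9.0, -10.0)},
    "CERR": {"VH": (-13.0, -14.0), "VV": (-8.5, -9.0)},
    "V":    {"VH": (-12.0, -12.5), "VV": (-7.0, -7.5)},
    "C":    {"VH": (-11.0, -11.5), "VV": (-7.0, -7.2)},
    "MG":   {"VH": (-10.0, -10.5), "VV": (-6.5, -6.7)},
    "PAST": {"VH": (-17.0, -19.5), "VV": (-10.0, -12.5)},
    "PF":   {"VH": (-10.5, -10.8), "VV": (-6.8, -7.0)},
    "A":    {"VH": (-15.0, -20.0), "VV": (-9.0, -14.0)},
    "W":    {"VH": (-24.0, -24.0), "VV": (-18.0, -18.0)},
    "NV":   {"VH": (-20.0, -20.0), "VV": (-13.0, -13.0)},
}
# recently burned surface: low NIR / red edge, SWIR2 raised above SWIR1
_CHAR = _spectrum(.040, .050, .060, .100, .300, .340)

_DEFAULT_FRACTIONS = {
    "CSS": 0.20, "CERR": 0.10, "CS": 0.10, "CLU": 0.07, "CAMR": 0.07,
    "C": 0.06, "MG": 0.03, "V": 0.01, "PAST": 0.12, "PF": 0.04, "A": 0.08,
    "W": 0.02, "NV": 0.10,
}

#: classes drawn as riparian/drainage features rather than upland patches
_CORRIDOR_CLASSES = ("CLU", "MG", "V")
#: classes biased onto high-slope terrain
_RUPESTRIAN = ("CAMR", "CERR")


def default_scene_config(rows: int = 200, cols: int = 200,
                         sd: float = 0.010, seed: int = 0,
                         **overrides) -> SceneConfig:
    """A 13-class scene with well-separated signatures.

    ``sd`` is the per-band reflectance noise; the anchor spectra are spaced
    so that every class pair differs by at least ~3 sd in some band at the
    default sd.
    """
    optical = {c: {b: (_WET[c][b], _DRY[c][b], sd) for b in OPTICAL_BANDS}
               for c in _WET}
    return SceneConfig(
        rows=rows, cols=cols,
        class_fractions=dict(_DEFAULT_FRACTIONS),
        optical_signatures=optical, sar_signatures=dict(_SAR),
        seed=seed, **overrides)


def phenology_scene_config(rows: int = 120, cols: int = 120,
                           sd: float = 0.010, seed: int = 0,
                           **overrides) -> SceneConfig:
    """A scene whose physiognomies differ chiefly in wet/dry phenology.

    Within each native formation the physiognomies share one mid-season
    spectrum and differ only in the amplitude (and sign) of their seasonal
    swing, so annual-statistic feature spaces see nearly identical classes
    while seasonal feature spaces separate them.
    """
    cfg = default_scene_config(rows, cols, sd=sd, seed=seed, **overrides)
    optical = {c: dict(s) for c, s in cfg.optical_signatures.items()}
    sar = {c: dict(s) for c, s in cfg.sar_signatures.items()}
    # seasonal NIR/Red amplitude per physiognomy, applied around the
    # formation's common mid spectrum
    amp = {"CLU": 0.06, "CS": 0.00, "CAMR": -0.06,
           "CSS": 0.06, "CERR": 0.00, "V": -0.06,
           "C": 0.05, "MG": -0.05}
    mid = {"GRA": _spectrum(.035, .065, .075, .300, .260, .160),
           "SAV": _spectrum(.038, .062, .080, .290, .270, .175),
           "FOR": _spectrum(.022, .044, .038, .390, .190, .100)}
    sar_mid = {"GRA": {"VH": -18.0, "VV": -10.5},
               "SAV": {"VH": -13.5, "VV": -9.0},
               "FOR": {"VH": -10.7, "VV": -6.9}}
    for cls, a in amp.items():
        formation = DEFAULT_SCHEME.formation(cls)
        base = mid[formation]
        sig = {}
        for b in OPTICAL_BANDS:
            swing = a if b in ("NIR", "RE1", "RE2", "RE3", "RE4") else \
                (-a / 2 if b == "Red" else 0.0)
            sig[b] = (base[b] + swing, base[b] - swing, sd)
        optical[cls] = sig
        sar[cls] = {p: (sar_mid[formation][p] + 25 * a,
                        sar_mid[formation][p] - 25 * a)
                    for p in SAR_BANDS}
    return replace(cfg, optical_signatures=optical, sar_signatures=sar)


# ---------------------------------------------------------------------------
# terrain
# ---------------------------------------------------------------------------

def generate_terrain(config: SceneConfig, base_elevation: float = 500.0
                     ) -> RasterGrid:
    """Smooth random elevation surface; max-min equals the configured relief
    amplitude exactly, so doubling the amplitude doubles the range."""
    rng = _rng(config.seed, "terrain")
    g = ndimage.gaussian_filter(
        rng.standard_normal(config.grid.shape), sigma=12, mode="reflect")
    span = g.max() - g.min()
    if span > 0 and config.relief_amplitude > 0:
        g = (g - g.min()) / span * config.relief_amplitude
    else:
        g = np.zeros_like(g)
    return RasterGrid(g + base_elevation, config.grid, name="DEM")


def _horn_slope_deg(elev: np.ndarray, pixel_size: float) -> np.ndarray:
    z = np.pad(elev, 1, mode="edge")
    dzdx = ((z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
            - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])) / (8 * pixel_size)
    dzdy = ((z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
            - (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])) / (8 * pixel_size)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _drainage_path(rng: np.random.Generator, rows: int, cols: int,
                   length: int) -> tuple[np.ndarray, np.ndarray]:
    """A meandering line across the grid: a principal direction with
    lateral jitter."""
    vertical = rng.random() < 0.5
    n_main = rows if vertical else cols
    start_main = int(rng.integers(0, n_main))
    cross = float(rng.integers(0, cols if vertical else rows))
    main_idx, cross_idx = [], []
    m, x = start_main, cross
    for _ in range(length):
        main_idx.append(m)
        cross_idx.append(int(round(x)))
        m += 1
        x += rng.normal(0, 0.7)
        x = min(max(x, 0), (cols if vertical else rows) - 1)
        if m >= n_main:
            break
    mi = np.array(main_idx)
    ci = np.array(cross_idx)
    return (mi, ci) if vertical else (ci, mi)


def _paint_corridor(canvas: np.ndarray, rows_cols, code: int,
                    half_width: int) -> None:
    mask = np.zeros(canvas.shape, bool)
    mask[rows_cols] = True
    if half_width > 0:
        mask = ndimage.binary_dilation(
            mask, structure=ndimage.generate_binary_structure(2, 2),
            iterations=half_width)
    canvas[mask] = code


def generate_landscape(config: SceneConfig,
                       scheme: ClassScheme = DEFAULT_SCHEME) -> LabelGrid:
    """Synthesise the ground-truth class mosaic.

    Riparian classes (CLU, MG) are corridors along synthetic drainage
    lines; vereda (V) stands are small clusters embedded inside the CLU
    corridors (so every V pixel is one pixel from CLU by construction);
    rupestrian classes (CAMR, CERR) are biased onto high-slope cells of the
    paired terrain; the remaining classes are smoothed-categorical-noise
    patches calibrated to the requested fractions. Any unallocated
    probability mass becomes non-vegetated (NV).
    """
    rng = _rng(config.seed, "landscape")
    rows, cols = config.rows, config.cols
    n_pix = rows * cols
    fr = dict(config.class_fractions)
    leftover = 1.0 - sum(fr.values())
    if leftover > 1e-9:
        fr["NV"] = fr.get("NV", 0.0) + leftover

    for cls, f in fr.items():
        if cls not in scheme.terminal_classes:
            raise ValueError(f"unknown class {cls!r} in fractions")
        if f > 0 and f * n_pix < 4:
            raise ValueError(
                f"grid too small to host class {cls!r} "
                f"(target {f * n_pix:.1f} pixels)")

    canvas = np.zeros((rows, cols), dtype=np.int16)  # 0 = unassigned
    # --- riparian corridors ------------------------------------------------
    corridor_halfwidth = {"CLU": 2, "MG": 1}
    for cls in ("CLU", "MG"):
        target = fr.get(cls, 0.0) * n_pix
        if cls == "CLU":
            # vereda stands are carved out of the CLU corridors later
            target += fr.get("V", 0.0) * n_pix
        if target <= 0:
            continue
        code = scheme.code_of[cls]
        guard = 0
        while (canvas == code).sum() < 0.97 * target and guard < 400:
            guard += 1
            width_px = 2 * corridor_halfwidth[cls] + 1
            need = target - (canvas == code).sum()
            length = int(min(max(rows, cols), max(8, need / width_px)))
            path = _drainage_path(rng, rows, cols, length)
            _paint_corridor(canvas, path, code, corridor_halfwidth[cls])

    # --- vereda stands inside CLU corridors --------------------------------
    v_target = fr.get("V", 0.0) * n_pix
    if v_target > 0:
        clu_code = scheme.code_of["CLU"]
        v_code = scheme.code_of["V"]
        clu_cells = np.argwhere(canvas == clu_code)
        if clu_cells.size == 0:
            raise ValueError(
                "cannot place vereda stands: no campo limpo umido corridor "
                "(set a positive CLU fraction)")
        guard = 0
        while (canvas == v_code).sum() < 0.8 * v_target and guard < 4000:
            guard += 1
            r, c = clu_cells[rng.integers(len(clu_cells))]
            rr = slice(max(r - 1, 0), min(r + 1, rows))
            cc = slice(max(c - 1, 0), min(c + 1, cols))
            block = canvas[rr, cc]
            block[block == clu_code] = v_code
        # keep every V pixel adjacent to remaining CLU: stands are 2x2 or
        # smaller inside a 5-wide corridor, so CLU survives alongside; any
        # stand that exhausted its local CLU is reverted
        v_mask = canvas == v_code
        clu_near = ndimage.binary_dilation(
            canvas == clu_code, structure=np.ones((3, 3), bool),
            iterations=2)
        canvas[v_mask & ~clu_near] = clu_code

    # --- upland patches ----------------------------------------------------
    upland = [c for c, f in sorted(fr.items())
              if f > 0 and c not in _CORRIDOR_CLASSES]
    if not upland:
        raise ValueError("no upland classes requested")
    free = canvas == 0
    n_free = int(free.sum())
    shares = np.array([fr[c] for c in upland])
    shares = shares / shares.sum()

    terrain = generate_terrain(config)
    slope = _horn_slope_deg(terrain.values, config.pixel_size)
    slope_z = (slope - slope.mean()) / (slope.std() + 1e-12)

    fields = []
    for cls in upland:
        g = ndimage.gaussian_filter(
            rng.standard_normal((rows, cols)), sigma=4, mode="reflect")
        g = g / (g.std() + 1e-12)
        if cls in _RUPESTRIAN:
            g = g + 0.8 * slope_z
        fields.append(g)
    fields = np.stack(fields)  # (n_classes, rows, cols)

    bias = np.zeros(len(upland))
    for _ in range(60):
        lab = np.argmax(fields + bias[:, None, None], axis=0)
        realized = np.array([(lab[free] == i).mean()
                             for i in range(len(upland))])
        err = shares - realized
        if np.all(np.abs(err) <= 0.08 * shares + 1e-4):
            break
        bias += 0.6 * (np.log(shares + 1e-6) - np.log(realized + 1e-6))
    lab = np.argmax(fields + bias[:, None, None], axis=0)
    for i, cls in enumerate(upland):
        canvas[free & (lab == i)] = scheme.code_of[cls]

    return LabelGrid(canvas, config.grid, scheme)


# ---------------------------------------------------------------------------
# burn history
# ---------------------------------------------------------------------------

#: relative likelihood of a scar per calendar month (late dry / early wet
#: season fires dominate)
_BURN_MONTH_WEIGHTS = np.array(
    [1, 1, 1, 2, 3, 5, 8, 14, 18, 14, 6, 2], dtype=float)


def generate_burn_history(labels: LabelGrid, config: SceneConfig
                          ) -> BurnHistory:
    """Contiguous elliptical burn scars concentrated in the fire season;
    the union of all scars covers approximately ``config.burn_fraction`` of
    the grid."""
    rng = _rng(config.seed, "burns")
    rows, cols = labels.grid.shape
    n_pix = rows * cols
    masks = [np.zeros((rows, cols), bool) for _ in range(12)]
    scars: list[tuple[int, float]] = []
    if config.burn_fraction <= 0:
        return BurnHistory(masks, scars, labels.grid)
    target = config.burn_fraction * n_pix
    p = _BURN_MONTH_WEIGHTS / _BURN_MONTH_WEIGHTS.sum()
    union = np.zeros((rows, cols), bool)
    yy, xx = np.mgrid[0:rows, 0:cols]
    guard = 0
    while union.sum() < target and guard < 5000:
        guard += 1
        month = int(rng.choice(12, p=p)) + 1
        cr, cc = rng.integers(rows), rng.integers(cols)
        a = max(2.0, rng.lognormal(np.log(max(3.0, 0.02 * rows)), 0.4))
        b = a * rng.uniform(0.4, 1.0)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cr, xx - cc
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        scar = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        new = scar & ~union
        if union.sum() + new.sum() > 1.15 * target and new.sum() > 0.2 * target:
            continue  # would badly overshoot; try a smaller scar
        masks[month - 1] |= scar
        union |= scar
        scars.append((month, float(scar.sum())
                      * labels.grid.pixel_size ** 2))
    return BurnHistory(masks, scars, labels.grid)


# ---------------------------------------------------------------------------
# imagery
# ---------------------------------------------------------------------------

def _cloud_mask(rng: np.random.Generator, shape, fraction: float
                ) -> np.ndarray:
    if fraction <= 0:
        return np.zeros(shape, bool)
    if fraction >= 1:
        return np.ones(shape, bool)
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=6,
                                mode="reflect")
    thresh = np.quantile(g, 1.0 - fraction)
    return g >= thresh


def generate_image_collections(
        labels: LabelGrid, config: SceneConfig,
        climatology: MonthlyClimatology,
        burn_history: BurnHistory | None = None,
        season_threshold_mm: float = 100.0,
        ) -> tuple[ImageCollection, ImageCollection]:
    """One optical (10-band) and one SAR (VH/VV dB) scene per month.

    Pixel values ~ Normal(class seasonal mean, sd); the seasonal mean is the
    wet or dry anchor according to the month's climatology season. Cloud
    masks (random blobs at the configured fraction) attach to optical
    scenes only. Pixels burned in month m take the post-burn char spectrum
    for months m and m+1.
    """
    if labels.grid.shape != config.grid.shape:
        raise ValueError("label grid does not match scene config grid")
    rng = _rng(config.seed, "imagery")
    cloud_rng = _rng(config.seed, "clouds")
    scheme = labels.scheme
    dry_months = {m + 1 for m, p in enumerate(climatology.precip_mm)
                  if p < season_threshold_mm}

    present = [c for c in scheme.terminal_classes
               if np.any(labels.values == scheme.code_of[c])]
    class_idx = {c: i for i, c in enumerate(present)}
    idx_map = np.full(labels.grid.shape, -1, dtype=np.int32)
    for c, i in class_idx.items():
        idx_map[labels.values == scheme.code_of[c]] = i

    recently_burned = [np.zeros(labels.grid.shape, bool) for _ in range(12)]
    if burn_history is not None:
        for m0, mask in enumerate(burn_history.masks):
            for m in (m0, m0 + 1):
                if m < 12:
                    recently_burned[m] |= mask

    optical_scenes, sar_scenes = [], []
    for month in range(1, config.n_months + 1):
        season = 1 if month in dry_months else 0  # 0 = wet anchor
        bands: dict[str, np.ndarray] = {}
        for band in OPTICAL_BANDS:
            means = np.array([
                config.optical_signatures[c][band][season] for c in present])
            sds = np.array([
                config.optical_signatures[c][band][2] for c in present])
            img = means[idx_map] + sds[idx_map] * rng.standard_normal(
                labels.grid.shape)
            burned = recently_burned[month - 1]
            if burned.any():
                sd_b = sds[idx_map][burned]
                img[burned] = _CHAR[band] + sd_b * rng.standard_normal(
                    int(burned.sum()))
            bands[band] = np.clip(img, 0.0, 1.0)
        mask = _cloud_mask(cloud_rng, labels.grid.shape,
                           config.cloud_fraction)
        optical_scenes.append((month, bands, mask))

        sar_bands = {}
        for pol in SAR_BANDS:
            means = np.array([
                config.sar_signatures[c][pol][season] for c in present])
            sar_bands[pol] = means[idx_map] + config.sar_sd * \
                rng.standard_normal(labels.grid.shape)
        sar_scenes.append((month, sar_bands, None))

    return (ImageCollection(labels.grid, optical_scenes),
            ImageCollection(labels.grid, sar_scenes))


# ---------------------------------------------------------------------------
# reference sites
# ---------------------------------------------------------------------------

def generate_reference_sites(labels: LabelGrid, n_per_class: int = 10,
                             seed: int = 0,
                             classes: list[str] | None = None
                             ) -> list[ReferenceZone]:
    """Pure-class reference zones strictly inside patches.

    Grassland physiognomies get square delineated polygons (half-width
    25 m); vereda and gallery forest get 12 m point buffers; everything
    else gets 30 m point buffers. A site pixel is eligible when its
    distance to the nearest other-class pixel exceeds the zone's reach, so
    every zone is pure by construction.
    """
    rng = _rng(seed, "sites")
    scheme = labels.scheme
    px = labels.grid.pixel_size
    if classes is None:
        classes = [c for c in scheme.terminal_classes
                   if np.any(labels.values == scheme.code_of[c])]
    zones: list[ReferenceZone] = []
    zone_id = 0
    for cls in classes:
        mask = labels.values == scheme.code_of[cls]
        if not mask.any():
            raise ValueError(f"class {cls!r} absent from the label grid")
        is_gra = cls in scheme.physiognomies and \
            scheme.formation(cls) == "GRA"
        if is_gra:
            reach = 25.0 * np.sqrt(2)  # half-diagonal of the square
        elif cls in ("V", "MG"):
            reach = 12.0
        else:
            reach = 30.0
        edt = ndimage.distance_transform_edt(mask) * px
        eligible = np.argwhere(edt > reach)
        if len(eligible) == 0:
            raise ValueError(
                f"no eligible interior pixels for class {cls!r} "
                f"(patches too small for a {reach:.0f} m zone)")
        n_take = min(n_per_class, len(eligible))
        if n_take < n_per_class:
            warnings.warn(
                f"class {cls}: only {n_take} of {n_per_class} requested "
                "sites available")
        pick = rng.choice(len(eligible), size=n_take, replace=False)
        xs, ys = labels.grid.pixel_centers()
        for k in pick:
            r, c = eligible[k]
            x, y = xs[r, c], ys[r, c]
            zone_id += 1
            if is_gra:
                geom = box(x - 25.0, y - 25.0, x + 25.0, y + 25.0)
                zones.append(ReferenceZone(zone_id, cls, geom))
            else:
                zones.append(ReferenceZone(zone_id, cls, Point(x, y),
                                           radius=reach))
    return zones
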