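"""Reference zones, burned-zone quality control and zone-based splits.

Field reference sites are *zones* — a GPS point with a class-specific buffer
radius, or a hand-delineated polygon — rasterised to the pixels whose
centres they cover. Quality control drops any zone pixel that burned during
the imagery period. Train/validation splitting always operates on zone ids,
never raw pixels, so spatially autocorrelated pixels of one site can never
leak between train and validation sets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Point, shape, mapping
from shapely.geometry.base import BaseGeometry

from .raster import GridSpec
from .scheme import ClassScheme, DEFAULT_SCHEME

__all__ = [
    "ReferenceZone", "ReferenceSample", "default_buffer_radius",
    "rasterize_zones", "mask_burned_zones", "split_zones",
    "draw_training_zones", "zones_to_geojson", "zones_from_geojson",
]


@dataclass(frozen=True)
class ReferenceZone:
    """A labelled field site: point + buffer radius, or a polygon."""

    zone_id: int
    terminal_class: str
    geometry: BaseGeometry  # polygon, or Point when radius is set
    radius: float | None = None  # metres; None for polygon zones
    year: int | None = None

    def __post_init__(self) -> None:
        if self.radius is not None and self.radius <= 0:
            raise ValueError("buffer radius must be > 0")

    @property
    def footprint(self) -> BaseGeometry:
        """Polygon the zone occupies (point zones buffered by radius)."""
        if self.radius is not None:
            return self.geometry.buffer(self.radius)
        return self.geometry


@dataclass(frozen=True)
class ReferenceSample:
    """One reference pixel: location, labels, provenance, QC status."""

    row: int
    col: int
    terminal_class: str
    formation_class: str
    zone_id: int
    burn_masked: bool = False


def default_buffer_radius(cls: str, scheme: ClassScheme = DEFAULT_SCHEME,
                          radius: float | None = None) -> float:
    """Buffer radius (m) for a point-based reference site of class ``cls``.

    Vereda and gallery-forest sites are centred on narrow linear features
    (palm stands, riparian strips), so they take a small 12 m buffer that in
    most cases samples a single 20 m pixel. Other savanna/forest
    physiognomies default to 30 m, overridable within [20, 40]. Grassland
    physiognomies have no default radius: their reference areas are
    delineated as free-form polygons and must be supplied as such.
    """
    if cls in ("V", "MG"):
        if radius is not None and radius != 12:
            raise ValueError(f"{cls} reference zones use a fixed 12 m buffer")
        return 12.0
    if cls in scheme.physiognomies and scheme.formation(cls) == "GRA":
        raise ValueError(
            f"grassland class {cls!r} requires a delineated polygon zone, "
            "not a buffered point")
    if radius is None:
        return 30.0
    if cls in scheme.physiognomies and not (20.0 <= radius <= 40.0):
        raise ValueError(
            f"buffer radius for {cls} must lie in [20, 40] m, got {radius}")
    return float(radius)


def rasterize_zones(zones: list[ReferenceZone], grid: GridSpec,
                    scheme: ClassScheme = DEFAULT_SCHEME
                    ) -> list[ReferenceSample]:
    """Pixels whose centres fall inside each zone's footprint.

    A pixel claimed by zones of *different* classes is discarded with a
    warning (reference purity over sample count); zones entirely off-grid
    are skipped with a warning.
    """
    claims: dict[tuple[int, int], list[ReferenceZone]] = {}
    xs, ys = grid.pixel_centers()
    for zone in zones:
        geom = zone.footprint
        minx, miny, maxx, maxy = geom.bounds
        r0, c0 = grid.xy_to_rowcol(minx, maxy)
        r1, c1 = grid.xy_to_rowcol(maxx, miny)
        r0, r1 = max(r0, 0), min(r1, grid.rows - 1)
        c0, c1 = max(c0, 0), min(c1, grid.cols - 1)
        if r0 > r1 or c0 > c1:
            warnings.warn(f"zone {zone.zone_id} lies off-grid; skipped")
            continue
        sub_x = xs[r0:r1 + 1, c0:c1 + 1]
        sub_y = ys[r0:r1 + 1, c0:c1 + 1]
        inside = shapely.contains_xy(geom, sub_x.ravel(), sub_y.ravel())
        rr, cc = np.nonzero(inside.reshape(sub_x.shape))
        if rr.size == 0:
            warnings.warn(f"zone {zone.zone_id} covers no pixel centre")
            continue
        for r, c in zip(rr + r0, cc + c0):
            claims.setdefault((int(r), int(c)), []).append(zone)

    samples: list[ReferenceSample] = []
    n_conflict = 0
    for (r, c), zs in sorted(claims.items()):
        classes = {z.terminal_class for z in zs}
        if len(classes) > 1:
            n_conflict += 1
            continue
        z = zs[0]
        samples.append(ReferenceSample(
            r, c, z.terminal_class, scheme.formation(z.terminal_class),
            z.zone_id))
    if n_conflict:
        warnings.warn(
            f"discarded {n_conflict} pixels claimed by zones of different "
            "classes")
    return samples


def mask_burned_zones(samples: list[ReferenceSample],
                      burn_masks: list[np.ndarray],
                      scheme: ClassScheme = DEFAULT_SCHEME
                      ) -> tuple[list[ReferenceSample], dict[str, float]]:
    """Flag reference pixels that burned in any month of the imagery period.

    Returns the samples (burned ones flagged ``burn_masked=True``; callers
    must exclude flagged samples from training and validation) and the
    percentage reduction in available pixels per formation-level group.
    """
    if burn_masks:
        burned_any = np.any(np.stack(burn_masks), axis=0)
    else:
        burned_any = None
    out = []
    for s in samples:
        flag = bool(burned_any[s.row, s.col]) if burned_any is not None \
            else False
        out.append(ReferenceSample(s.row, s.col, s.terminal_class,
                                   s.formation_class, s.zone_id, flag))
    reduction: dict[str, float] = {}
    for group in scheme.stage1_classes:
        tot = sum(1 for s in out if s.formation_class == group)
        cut = sum(1 for s in out if s.formation_class == group
                  and s.burn_masked)
        reduction[group] = 100.0 * cut / tot if tot else 0.0
    return out, reduction


def active_samples(samples: list[ReferenceSample]) -> list[ReferenceSample]:
    """Samples that survived burn masking."""
    return [s for s in samples if not s.burn_masked]


def split_zones(samples: list[ReferenceSample], withhold_fraction: float = 0.2,
                seed: int | np.random.Generator = 0,
                ) -> tuple[set[int], set[int]]:
    """Withhold a class-stratified validation set of zones.

    Per terminal class, ``max(1, round(withhold_fraction * n_zones))`` zones
    go to validation; the rest form the training pool. Splitting is by zone
    id so the two sets are zone-disjoint by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for s in active_samples(samples):
        zl = by_class.setdefault(s.terminal_class, [])
        if s.zone_id not in zl:
            zl.append(s.zone_id)
    val: set[int] = set()
    pool: set[int] = set()
    for cls in sorted(by_class):
        zids = sorted(by_class[cls])
        if len(zids) < 2:
            raise ValueError(
                f"class {cls!r} has {len(zids)} zone(s); at least 2 are "
                "needed to split")
        n_hold = max(1, round(withhold_fraction * len(zids)))
        held = rng.choice(zids, size=n_hold, replace=False)
        val.update(int(z) for z in held)
        pool.update(z for z in zids if z not in set(int(h) for h in held))
    return val, pool


def draw_training_zones(pool_zones_by_class: dict[str, list[int]],
                        train_fraction: float,
                        rng: np.random.Generator) -> set[int]:
    """One inner-run draw: a fresh random ``train_fraction`` of pool zones
    per class (at least 1 zone per class)."""
    train: set[int] = set()
    for cls in sorted(pool_zones_by_class):
        zids = sorted(pool_zones_by_class[cls])
        n = max(1, round(train_fraction * len(zids)))
        pick = rng.choice(zids, size=min(n, len(zids)), replace=False)
        train.update(int(z) for z in pick)
    return train


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def zones_to_geojson(zones: list[ReferenceZone], path: str | Path) -> Path:
    path = Path(path)
    feats = []
    for z in zones:
        props = {"zone_id": z.zone_id, "class": z.terminal_class}
        if z.radius is not None:
            props["radius_m"] = z.radius
        if z.year is not None:
            props["year"] = z.year
        feats.append({"type": "Feature", "geometry": mapping(z.geometry),
                      "properties": props})
    path.write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}, indent=1))
    return path


def zones_from_geojson(path: str | Path) -> list[ReferenceZone]:
    data = json.loads(Path(path).read_text())
    zones = []
    for feat in data["features"]:
        props = feat["properties"]
        zones.append(ReferenceZone(
            zone_id=int(props["zone_id"]),
            terminal_class=str(props["class"]),
            geometry=shape(feat["geometry"]),
            radius=props.get("radius_m"),
            year=props.get("year")))
    return zones
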