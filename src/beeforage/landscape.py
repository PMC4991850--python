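"""Landscape model, I/O, hive-site enumeration and scenario generators.

A landscape is a flat collection of patches with planar (metric)
geometry: large target-crop fields (the sprayed mass-flowering crop),
optional alternative-crop fields, and numerous small off-field elements
(verges, ditch sides).  Geometry is handled with shapely; files are
read and written as GeoJSON FeatureCollections or CSV with a WKT column.
No coordinate-reference-system handling is attempted — coordinates are
assumed to be metres in a local planar frame.

Candidate hive sites are the cells of a square grid (default 25 m) that
border a target-crop field (8-neighbour adjacency between a non-field
cell and a field cell); assessments run on a seeded random sample of
those sites, identical across scenarios for a given seed.

Three mitigation-scenario generators dress a landscape for one
realization:

* **alternative fields** — target fields treated i.i.d. Bernoulli(p),
  alternative-crop fields untreated with a sugar-content multiplier;
* **flower strips** — up to four clover strips per target field, each
  present with probability p, of width ``w`` along quarter-perimeter
  boundary segments; strip area is subtracted from the field;
* **off-field habitats** — each off-field element becomes a clover patch
  with probability p, with open-flower density scaled by a quality
  multiplier.

Presence/treatment draws use the form ``u_i < p`` with ``u_i`` drawn once
per patch from the realization seed, so realizations for increasing p are
nested when the seed is held fixed (useful for paired-seed monotonicity
analyses).

A seeded synthetic generator builds landscapes in the same mould as the
agricultural case this tool targets: tens of multi-hectare rectangular
fields plus hundreds of narrow linear off-field elements on a
several-kilometre extent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry import LineString, Point, Polygon, box, mapping, shape
from shapely.ops import substring
from shapely.strtree import STRtree
from shapely import wkt as shapely_wkt

from .params import CLOVER, OILSEED_RAPE, RESOURCE_PRESETS, ResourceType, clover_variant, osr_variant

__all__ = [
    "CATEGORIES",
    "LandPatch",
    "LandscapeSpec",
    "HiveSite",
    "ScenarioConfig",
    "RealizedPatch",
    "ScenarioRealization",
    "load_landscape",
    "save_landscape",
    "enumerate_hive_sites",
    "hive_patch_distance",
    "SyntheticLandscapeParams",
    "generate_synthetic_landscape",
    "scenario_alternative_fields",
    "scenario_flower_strips",
    "scenario_off_field",
]

CATEGORIES = ("target-field", "alternative-field", "flower-strip", "off-field")


@dataclass(frozen=True)
class LandPatch:
    """A polygonal (or linear) landscape element with attributes.

    ``area`` defaults to the geometry's area but can be stored explicitly
    (flower strips are represented by their boundary line plus an explicit
    width-times-length area).
    """

    id: str
    geometry: object  # shapely geometry
    category: str
    resource: Optional[str] = None
    area: Optional[float] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.area is None:
            object.__setattr__(self, "area", float(self.geometry.area))
        if self.area <= 0:
            raise ValueError(f"patch {self.id}: area must be positive")


@dataclass
class LandscapeSpec:
    """A patch collection plus the hive-site grid resolution."""

    patches: List[LandPatch]
    resolution: float = 25.0

    def by_category(self, category: str) -> List[LandPatch]:
        return [p for p in self.patches if p.category == category]

    def summary(self) -> pd.DataFrame:
        """Counts and total hectares per category."""
        rows = {}
        for p in self.patches:
            rec = rows.setdefault(p.category, {"count": 0, "total_ha": 0.0})
            rec["count"] += 1
            rec["total_ha"] += p.area / 1e4
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class HiveSite:
    """A candidate hive location: one grid cell bordering a target field."""

    x: float  # cell-centre coordinates, m
    y: float
    adjacent_patch_id: str  # the (always treated) bordering target field


# -- I/O ---------------------------------------------------------------------

def save_landscape(ls: LandscapeSpec, path: str) -> None:
    """Write a landscape as a GeoJSON FeatureCollection (or CSV-with-WKT)."""
    if str(path).endswith(".csv"):
        pd.DataFrame(
            {
                "id": [p.id for p in ls.patches],
                "category": [p.category for p in ls.patches],
                "resource": [p.resource for p in ls.patches],
                "area": [p.area for p in ls.patches],
                "wkt": [p.geometry.wkt for p in ls.patches],
            }
        ).to_csv(path, index=False)
        return
    features = [
        {
            "type": "Feature",
            "geometry": mapping(p.geometry),
            "properties": {
                "id": p.id,
                "category": p.category,
                "resource": p.resource,
                "area": p.area,
            },
        }
        for p in ls.patches
    ]
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "resolution": ls.resolution,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_landscape(source) -> LandscapeSpec:
    """Read a landscape from GeoJSON, CSV-with-WKT, or a dict already in memory.

    Validates geometry, category and resource names; patch areas are
    computed from the geometry when absent.
    """
    if isinstance(source, LandscapeSpec):
        return source
    if isinstance(source, dict):
        doc = source
        resolution = float(doc.get("resolution", 25.0))
        patches = []
        for i, feat in enumerate(doc["features"]):
            props = feat.get("properties", {})
            geom = shape(feat["geometry"])
            if not geom.is_valid:
                raise ValueError(f"feature {i}: invalid geometry")
            patches.append(_make_patch(props, geom, i))
        return LandscapeSpec(patches=patches, resolution=resolution)
    path = str(source)
    if path.endswith(".csv"):
        df = pd.read_csv(path)
        patches = []
        for i, row in df.iterrows():
            geom = shapely_wkt.loads(row["wkt"])
            props = {
                "id": row.get("id", f"p{i}"),
                "category": row["category"],
                "resource": row.get("resource"),
                "area": row.get("area"),
            }
            patches.append(_make_patch(props, geom, i))
        return LandscapeSpec(patches=patches)
    with open(path) as fh:
        return load_landscape(json.load(fh))


def _make_patch(props: dict, geom, i: int) -> LandPatch:
    resource = props.get("resource")
    if resource is not None and not (isinstance(resource, float) and math.isnan(resource)):
        if resource not in RESOURCE_PRESETS and not resource.startswith(
            ("osr_", "clover_")
        ):
            raise ValueError(f"feature {i}: unknown resource {resource!r}")
    else:
        resource = None
    area = props.get("area")
    if area is not None and (isinstance(area, float) and math.isnan(area)):
        area = None
    return LandPatch(
        id=str(props.get("id", f"p{i}")),
        geometry=geom,
        category=props["category"],
        resource=resource,
        area=None if area is None else float(area),
    )


# -- hive sites and distances ------------------------------------------------

def enumerate_hive_sites(
    ls: LandscapeSpec,
    sample_fraction: float = 0.10,
    seed: Optional[int] = None,
) -> List[HiveSite]:
    """All grid cells bordering a target-crop field, optionally sampled.

    A cell belongs to a field when its centre falls inside the field
    polygon; a candidate site is a non-field cell 8-adjacent to a field
    cell.  ``sample_fraction`` < 1 returns a seeded random subset whose
    membership depends only on the landscape and the seed, so the same
    sample is reused across scenarios.
    """
    targets = ls.by_category("target-field")
    if not targets:
        import warnings

        warnings.warn("landscape has no target-crop patches; no hive sites")
        return []
    res = ls.resolution
    minx = min(p.geometry.bounds[0] for p in targets) - 2 * res
    miny = min(p.geometry.bounds[1] for p in targets) - 2 * res
    maxx = max(p.geometry.bounds[2] for p in targets) + 2 * res
    maxy = max(p.geometry.bounds[3] for p in targets) + 2 * res
    nx = int(math.ceil((maxx - minx) / res))
    ny = int(math.ceil((maxy - miny) / res))
    cx = minx + (np.arange(nx) + 0.5) * res
    cy = miny + (np.arange(ny) + 0.5) * res
    xx, yy = np.meshgrid(cx, cy, indexing="ij")

    field_mask = np.zeros((nx, ny), dtype=bool)
    for p in targets:
        b = p.geometry.bounds
        i0 = max(0, int((b[0] - minx) / res) - 1)
        i1 = min(nx, int((b[2] - minx) / res) + 2)
        j0 = max(0, int((b[1] - miny) / res) - 1)
        j1 = min(ny, int((b[3] - miny) / res) + 2)
        sub_x = xx[i0:i1, j0:j1]
        sub_y = yy[i0:i1, j0:j1]
        field_mask[i0:i1, j0:j1] |= contains_xy(p.geometry, sub_x, sub_y)

    neigh = ndimage.binary_dilation(field_mask, structure=np.ones((3, 3), bool))
    site_mask = neigh & ~field_mask
    idx = np.argwhere(site_mask)

    tree = STRtree([p.geometry for p in targets])
    sites: List[HiveSite] = []
    for i, j in idx:
        pt = Point(cx[i], cy[j])
        nearest = int(tree.nearest(pt))
        sites.append(HiveSite(x=float(cx[i]), y=float(cy[j]), adjacent_patch_id=targets[nearest].id))
    sites.sort(key=lambda s: (s.x, s.y))

    if sample_fraction < 1.0:
        rng = np.random.default_rng(seed)
        k = max(1, int(round(sample_fraction * len(sites))))
        chosen = rng.choice(len(sites), size=k, replace=False)
        sites = [sites[i] for i in sorted(chosen)]
    return sites


def hive_patch_distance(site: HiveSite, geometry, resolution: float = 25.0) -> float:
    """Euclidean distance (m) from the site-cell centre to the patch.

    Floored at half a grid cell so the field a hive stands against keeps a
    small but non-zero travel distance (avoids a D = 0 singularity in
    attractiveness while keeping the adjacent field near-optimal).
    """
    d = Point(site.x, site.y).distance(geometry)
    return max(d, resolution / 2.0)


# -- synthetic landscapes ----------------------------------------------------

@dataclass
class SyntheticLandscapeParams:
    """Knobs for the synthetic landscape generator.

    Defaults emulate an intensive arable landscape on a 5 × 5 km extent:
    ~50 rectangular target-crop fields of 2–10 ha, ~20 alternative-crop
    fields of the same size class, and ~500 narrow linear off-field
    elements (road verges, ditch banks) of 50–300 m by 2–6 m.  With
    ``target_total_ha`` set, field dimensions are rescaled so the summed
    target-crop area matches it.
    """

    extent: float = 5000.0
    n_target: int = 50
    n_alternative: int = 20
    n_offfield: int = 500
    field_area_ha: Tuple[float, float] = (2.0, 10.0)
    offfield_length_m: Tuple[float, float] = (50.0, 300.0)
    offfield_width_m: Tuple[float, float] = (2.0, 6.0)
    target_total_ha: Optional[float] = None
    resolution: float = 25.0
    max_tries: int = 200


def _place_rect(rng, extent, w, h, existing: List[Polygon], max_tries: int) -> Polygon:
    for _ in range(max_tries):
        x = rng.uniform(0, extent - w)
        y = rng.uniform(0, extent - h)
        rect = box(x, y, x + w, y + h)
        if all(not rect.intersects(e) for e in existing):
            return rect
    raise RuntimeError(
        f"could not place a {w:.0f}x{h:.0f} m rectangle after {max_tries} tries; "
        "reduce counts or field sizes relative to the extent"
    )


def generate_synthetic_landscape(
    params: Optional[SyntheticLandscapeParams] = None, seed: Optional[int] = None
) -> LandscapeSpec:
    """Seeded synthetic landscape with target fields, alternative fields
    and off-field elements.

    Fields are non-overlapping axis-aligned rectangles; off-field elements
    are thin rectangles that may abut (but not overlap) fields.  The same
    seed reproduces the landscape exactly.
    """
    params = params or SyntheticLandscapeParams()
    rng = np.random.default_rng(seed)
    patches: List[LandPatch] = []
    placed: List[Polygon] = []

    def field_dims(n):
        areas = rng.uniform(*params.field_area_ha, size=n) * 1e4
        aspect = rng.uniform(0.5, 2.0, size=n)
        w = np.sqrt(areas * aspect)
        h = areas / w
        return w, h, areas

    w_t, h_t, areas_t = field_dims(params.n_target)
    if params.target_total_ha is not None:
        scale = math.sqrt(params.target_total_ha * 1e4 / areas_t.sum())
        w_t, h_t = w_t * scale, h_t * scale
    for k in range(params.n_target):
        rect = _place_rect(rng, params.extent, w_t[k], h_t[k], placed, params.max_tries)
        placed.append(rect)
        patches.append(
            LandPatch(id=f"t{k:04d}", geometry=rect, category="target-field",
                      resource=OILSEED_RAPE.name)
        )

    w_a, h_a, _ = field_dims(params.n_alternative)
    for k in range(params.n_alternative):
        rect = _place_rect(rng, params.extent, w_a[k], h_a[k], placed, params.max_tries)
        placed.append(rect)
        patches.append(
            LandPatch(id=f"a{k:04d}", geometry=rect, category="alternative-field",
                      resource=OILSEED_RAPE.name)
        )

    field_tree = STRtree(placed) if placed else None
    lengths = rng.uniform(*params.offfield_length_m, size=params.n_offfield)
    widths = rng.uniform(*params.offfield_width_m, size=params.n_offfield)
    horiz = rng.random(params.n_offfield) < 0.5
    k_placed = 0
    for k in range(params.n_offfield):
        L, W = (lengths[k], widths[k]) if horiz[k] else (widths[k], lengths[k])
        for _ in range(params.max_tries):
            x = rng.uniform(0, params.extent - L)
            y = rng.uniform(0, params.extent - W)
            rect = box(x, y, x + L, y + W)
            if field_tree is None or not any(
                placed[i].intersects(rect) for i in field_tree.query(rect)
            ):
                patches.append(
                    LandPatch(id=f"o{k:04d}", geometry=rect, category="off-field",
                              resource=CLOVER.name)
                )
                k_placed += 1
                break
        else:
            raise RuntimeError(
                f"could not place off-field element {k} after {params.max_tries} tries"
            )
    return LandscapeSpec(patches=patches, resolution=params.resolution)


# -- scenario realizations ---------------------------------------------------

@dataclass(frozen=True)
class RealizedPatch:
    """A landscape patch dressed for one scenario realization.

    ``treated`` marks pesticide treatment; the chemical concentration is
    assigned at assessment time (treated → C_P).  ``area`` may differ from
    the underlying geometry (flower strips reduce their host field's
    area).
    """

    id: str
    geometry: object
    rt: ResourceType
    area: float
    category: str
    treated: bool


@dataclass
class ScenarioRealization:
    """One random realization of a mitigation scenario."""

    patches: List[RealizedPatch]
    scenario: str
    p: float
    seed: Optional[int]
    managed_area: float  # total area of added/managed resource patches, m^2


@dataclass
class ScenarioConfig:
    """Sweep definition for an assessment run."""

    scenario: str = "flower_strips"
    p_grid: Sequence[float] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 2))
    width: float = 2.0
    sugar_mult: float = 1.0
    quality_mult: float = 1.0
    realizations: int = 100
    site_sample_fraction: float = 0.10
    master_seed: int = 0


def _uniforms(rng: np.random.Generator, n: int) -> np.ndarray:
    # one uniform per element: presence/treatment = (u < p) so realizations
    # are nested across p for a fixed seed
    return rng.random(n)


def scenario_alternative_fields(
    ls: LandscapeSpec, p: float, sugar_mult: float = 1.0,
    seed: Optional[int] = None,
) -> ScenarioRealization:
    """Target fields treated i.i.d. Bernoulli(p); alternative fields
    untreated with sugar content scaled by ``sugar_mult``.

    The field adjacent to a hive is forced treated at assessment time
    regardless of its draw here.  Off-field elements are inert in this
    scenario.
    """
    rng = np.random.default_rng(seed)
    targets = ls.by_category("target-field")
    u = _uniforms(rng, len(targets))
    alt_rt = osr_variant(sugar_mult)
    patches = [
        RealizedPatch(
            id=t.id, geometry=t.geometry, rt=OILSEED_RAPE, area=t.area,
            category="target-field", treated=bool(u[i] < p),
        )
        for i, t in enumerate(targets)
    ]
    alt_area = 0.0
    for a in ls.by_category("alternative-field"):
        patches.append(
            RealizedPatch(
                id=a.id, geometry=a.geometry, rt=alt_rt, area=a.area,
                category="alternative-field", treated=False,
            )
        )
        alt_area += a.area
    return ScenarioRealization(
        patches=patches, scenario="alternative_fields", p=p, seed=seed,
        managed_area=alt_area,
    )


def scenario_flower_strips(
    ls: LandscapeSpec, p: float, w: float = 2.0, seed: Optional[int] = None,
) -> ScenarioRealization:
    """Clover strips of width ``w`` on target-field edges.

    Each target field hosts up to four candidate strips, one per
    quarter-perimeter boundary segment, each present with probability p.
    Strip area ``w × perimeter/4`` is subtracted from the field's area
    (the strips are in-field, off-crop habitat); the strip geometry is the
    boundary segment itself, which is what distance computations use.  All
    target fields are treated in this scenario.
    """
    rng = np.random.default_rng(seed)
    targets = ls.by_category("target-field")
    u = _uniforms(rng, 4 * len(targets)).reshape(len(targets), 4)
    patches: List[RealizedPatch] = []
    managed = 0.0
    for i, t in enumerate(targets):
        boundary = t.geometry.exterior if isinstance(t.geometry, Polygon) else t.geometry.boundary
        perim = boundary.length
        strip_len = perim / 4.0
        strip_area = w * strip_len
        present = u[i] < p
        n_strips = int(present.sum())
        if n_strips * strip_area >= t.area:
            raise ValueError(
                f"field {t.id}: strip area {n_strips * strip_area:.0f} m^2 "
                f">= field area {t.area:.0f} m^2"
            )
        for k in range(4):
            if not present[k]:
                continue
            seg = substring(LineString(boundary.coords), k * strip_len, (k + 1) * strip_len)
            patches.append(
                RealizedPatch(
                    id=f"{t.id}-strip{k}", geometry=seg, rt=CLOVER,
                    area=strip_area, category="flower-strip", treated=False,
                )
            )
            managed += strip_area
        patches.append(
            RealizedPatch(
                id=t.id, geometry=t.geometry, rt=OILSEED_RAPE,
                area=t.area - n_strips * strip_area, category="target-field",
                treated=True,
            )
        )
    return ScenarioRealization(
        patches=patches, scenario="flower_strips", p=p, seed=seed, managed_area=managed,
    )


def scenario_off_field(
    ls: LandscapeSpec, p: float, quality_mult: float = 1.0,
    seed: Optional[int] = None,
) -> ScenarioRealization:
    """Off-field elements become clover patches with probability p.

    Selected elements carry clover with open-flower density scaled by
    ``quality_mult`` (low/medium/high ≈ 0.5/1/1.5); unselected elements
    provide no nectar and are dropped.  All target fields are treated.
    """
    rng = np.random.default_rng(seed)
    rt = clover_variant(quality_mult) if quality_mult != 1.0 else CLOVER
    offs = ls.by_category("off-field")
    u = _uniforms(rng, len(offs))
    patches = [
        RealizedPatch(
            id=t.id, geometry=t.geometry, rt=OILSEED_RAPE, area=t.area,
            category="target-field", treated=True,
        )
        for t in ls.by_category("target-field")
    ]
    managed = 0.0
    for i, o in enumerate(offs):
        if u[i] < p:
            patches.append(
                RealizedPatch(
                    id=o.id, geometry=o.geometry, rt=rt, area=o.area,
                    category="off-field", treated=False,
                )
            )
            managed += o.area
    return ScenarioRealization(
        patches=patches, scenario="off_field", p=p, seed=seed, managed_area=managed,
    )
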