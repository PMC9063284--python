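"""The seven walkability components from raster and vector layers.

Components (per spatial unit, per scale):

* population density — inhabitants per hectare
* retail & service density — area share of the ``commercial`` and
  ``socio-cultural services`` land-use classes
* land-use mix — normalized Shannon entropy over five walking-relevant
  land-use classes (0 = single use, 1 = perfect mix)
* street connectivity — true intersections (>= 3 pedestrian-accessible
  legs) per km^2
* green space — area share of green/recreation land
* sidewalk density — area share of sidewalk
* public transport density — transit stops per km^2

Raw layers are rasterized to square cells (25 m default), smoothed with
circular-buffer focal statistics (150 / 500 / 1000 m radii) and sampled at
postal-code centroids, or aggregated by zonal statistics over
administrative neighbourhood polygons.  The land-use mix is always the
entropy of buffer-aggregated class shares, never the mean of cellwise
entropies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Polygon, box
from shapely.ops import unary_union
from shapely.prepared import prep

from .grids import GridLayer

log = logging.getLogger(__name__)

#: the five land-use classes relevant for the entropy index, in fixed order
LANDUSE_CLASSES = (
    "commercial",
    "socio_cultural",
    "residential",
    "offices_public",
    "green_recreation",
)

#: the seven component column names, in canonical order
COMPONENTS = (
    "population_density",
    "retail_service_density",
    "land_use_mix",
    "street_connectivity",
    "green_space",
    "sidewalk_density",
    "public_transport_density",
)

#: road classes treated as inaccessible to pedestrians by default
DEFAULT_INACCESSIBLE = frozenset({"highway", "motorway"})

M2_PER_KM2 = 1_000_000.0
M2_PER_HA = 10_000.0


@dataclass
class LandUseComposition:
    """Area shares over the five relevant land-use classes within a unit.

    ``p`` follows the class order of :data:`LANDUSE_CLASSES`; shares must be
    non-negative and sum to 1 whenever ``total_relevant_area`` is positive.
    """

    p: np.ndarray
    total_relevant_area: float = 1.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(LANDUSE_CLASSES),):
            raise ValueError(f"expected {len(LANDUSE_CLASSES)} shares, got {self.p.shape}")
        if np.any(self.p < 0):
            raise ValueError(f"negative land-use shares: {self.p}")
        if self.total_relevant_area > 0 and abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError(f"shares sum to {self.p.sum()!r}, not 1")


def land_use_entropy(comp: LandUseComposition) -> float:
    """Normalized Shannon entropy of land-use shares, in [0, 1].

    ``H = -sum_i p_i ln p_i / ln k`` with ``k = 5`` classes and the
    convention ``0 ln 0 = 0``.  1 means all five relevant classes occupy
    equal area ("perfect mix"); 0 means a single class holds everything.
    A unit with no relevant area at all has no defined mix and scores 0
    (logged).
    """
    if comp.total_relevant_area <= 0:
        log.warning("land_use_entropy: no relevant land-use area; returning 0")
        return 0.0
    p = comp.p
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz)) / np.log(len(LANDUSE_CLASSES))
    # clip fp noise so the documented [0, 1] range is exact
    return float(min(max(h, 0.0), 1.0))


# -- rasterization --------------------------------------------------------

def rasterize_area_fraction(polygons, template: GridLayer) -> GridLayer:
    """Per-cell area fraction covered by a polygon layer.

    ``polygons`` is an iterable of shapely polygons (or one geometry) in
    the template's planar frame; the result grid matches ``template``.
    Exact polygon/cell intersection areas are used (no sampling).
    """
    if template.values.size == 0:
        raise ValueError("empty grid template")
    geoms = [polygons] if isinstance(polygons, shapely.Geometry) else list(polygons)
    out = np.zeros((template.nrows, template.ncols), dtype=float)
    if not geoms:
        return template.like(out, "fraction")
    union = unary_union(geoms)
    cell = template.cell_m
    x0, y0 = template.origin
    minx, miny, maxx, maxy = union.bounds
    j0 = max(int(np.floor((minx - x0) / cell)), 0)
    j1 = min(int(np.floor((maxx - x0) / cell)) + 1, template.ncols)
    i0 = max(int(np.floor((miny - y0) / cell)), 0)
    i1 = min(int(np.floor((maxy - y0) / cell)) + 1, template.nrows)
    cell_area = cell * cell
    prepared = prep(union)
    for i in range(i0, i1):
        for j in range(j0, j1):
            b = box(x0 + j * cell, y0 + i * cell,
                    x0 + (j + 1) * cell, y0 + (i + 1) * cell)
            if prepared.contains(b):
                out[i, j] = 1.0
            elif prepared.intersects(b):
                out[i, j] = union.intersection(b).area / cell_area
    return template.like(np.clip(out, 0.0, 1.0), "fraction")


def rasterize_point_count(points: np.ndarray, template: GridLayer) -> GridLayer:
    """Count points per cell (half-open cell ownership).

    ``points`` is an ``(n, 2)`` array of x/y coordinates.  Points outside
    the grid extent are dropped; the number dropped is logged.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    out = np.zeros((template.nrows, template.ncols), dtype=float)
    if len(points):
        row, col, inside = template.cell_index(points[:, 0], points[:, 1])
        n_out = int((~inside).sum())
        if n_out:
            log.warning("rasterize_point_count: dropped %d point(s) outside extent", n_out)
        np.add.at(out, (row[inside], col[inside]), 1.0)
    return template.like(out, "count")


# -- street network -------------------------------------------------------

def extract_true_intersections(
    roads,
    inaccessible_classes=DEFAULT_INACCESSIBLE,
    noding_check_tolerance: float = 1e-3,
) -> np.ndarray:
    """Nodes where >= 3 pedestrian-accessible street legs meet.

    ``roads`` is an iterable of ``(LineString, road_class)`` pairs (or
    plain LineStrings, treated as accessible).  The network must be noded:
    segments meet only at exactly shared endpoints.  Node degree is the
    number of incident segment ends after removing inaccessible classes
    (highways etc.), so an arm's classification can demote a 4-leg crossing
    to a T or a through-node.

    Raises ``ValueError`` when two distinct endpoints lie within
    ``noding_check_tolerance`` metres of each other without coinciding —
    a symptom of an unnoded network; silent snapping would hide the data
    error (use :func:`snap_network` explicitly to repair).
    """
    degree: dict[tuple[float, float], int] = {}
    for item in roads:
        geom, cls = item if isinstance(item, tuple) else (item, "street")
        if cls in inaccessible_classes:
            continue
        coords = list(geom.coords)
        for pt in (coords[0], coords[-1]):
            key = (float(pt[0]), float(pt[1]))
            degree[key] = degree.get(key, 0) + 1
    if not degree:
        return np.empty((0, 2))
    nodes = np.array(list(degree.keys()))
    if len(nodes) > 1 and noding_check_tolerance > 0:
        tree = cKDTree(nodes)
        pairs = tree.query_pairs(noding_check_tolerance)
        if pairs:
            bad = sorted({tuple(nodes[i]) for p in pairs for i in p})
            raise ValueError(
                "network is not noded: endpoints nearly but not exactly "
                f"coincident at {bad[:10]}"
            )
    return np.array([pt for pt, deg in degree.items() if deg >= 3], dtype=float).reshape(-1, 2)


def snap_network(roads, tolerance: float):
    """Snap near-coincident segment endpoints together (optional repair step).

    Endpoints within ``tolerance`` metres are merged onto their cluster
    mean.  Returns a new list of ``(LineString, class)`` pairs.
    """
    items = [item if isinstance(item, tuple) else (item, "street")
             for item in roads]
    ends = []
    for geom, _ in items:
        c = list(geom.coords)
        ends.append(c[0])
        ends.append(c[-1])
    ends = np.asarray(ends, dtype=float)
    tree = cKDTree(ends)
    clusters = tree.query_ball_tree(tree, tolerance)
    snapped = ends.copy()
    for i, members in enumerate(clusters):
        snapped[i] = ends[members].mean(axis=0)
    out = []
    for k, (geom, cls) in enumerate(items):
        c = list(geom.coords)
        c[0] = tuple(snapped[2 * k])
        c[-1] = tuple(snapped[2 * k + 1])
        out.append((LineString(c), cls))
    return out


# -- focal & zonal statistics --------------------------------------------

def _kernel_offsets(radius_m: float, cell_m: float) -> list[tuple[int, int]]:
    """Cell offsets whose centres lie within ``radius_m`` of the focal centre."""
    r_cells = int(np.floor(radius_m / cell_m))
    offs = []
    for dy in range(-r_cells, r_cells + 1):
        for dx in range(-r_cells, r_cells + 1):
            if (dx * dx + dy * dy) * cell_m * cell_m <= radius_m * radius_m:
                offs.append((dy, dx))
    return offs


def focal_buffer_mean(layer: GridLayer, radius_m: float) -> GridLayer:
    """Circular-buffer focal mean; count layers come back as density per km^2.

    Each output cell is the mean over input cells whose centres lie within
    ``radius_m`` of the focal cell's centre.  At raster edges the
    denominator shrinks to the in-bounds kernel cells, so means stay
    unbiased.  For ``count`` layers the kernel mean (events per cell) is
    converted to events per km^2 by dividing by the cell area.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    if radius_m < layer.cell_m:
        warnings.warn(
            f"focal radius {radius_m} m is below the cell size {layer.cell_m} m; "
            "the kernel degenerates to the identity", stacklevel=2)
    vals = np.asarray(layer.values, dtype=float)
    nr, nc = vals.shape
    acc = np.zeros_like(vals)
    cnt = np.zeros(vals.shape, dtype=np.int64)
    # accumulate shifted copies offset-by-offset in a fixed order; a per-cell
    # loop over the same offset order produces bit-identical left-fold sums
    for dy, dx in _kernel_offsets(radius_m, layer.cell_m):
        # dst cell (i, j) accumulates src cell (i + dy, j + dx)
        dst_i0, dst_i1 = max(0, -dy), min(nr, nr - dy)
        dst_j0, dst_j1 = max(0, -dx), min(nc, nc - dx)
        if dst_i1 <= dst_i0 or dst_j1 <= dst_j0:
            continue
        src_i0, src_j0 = dst_i0 + dy, dst_j0 + dx
        acc[dst_i0:dst_i1, dst_j0:dst_j1] += vals[
            src_i0:src_i0 + (dst_i1 - dst_i0), src_j0:src_j0 + (dst_j1 - dst_j0)]
        cnt[dst_i0:dst_i1, dst_j0:dst_j1] += 1
    mean = acc / cnt
    if layer.semantics == "count":
        cell_area_km2 = layer.cell_m * layer.cell_m / M2_PER_KM2
        return layer.like(mean / cell_area_km2, "density")
    return layer.like(mean, layer.semantics)


def sample_at_centroids(layer: GridLayer, points: np.ndarray) -> np.ndarray:
    """Value of the cell containing each point (no interpolation).

    Points outside the extent yield NaN and are logged.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    row, col, inside = layer.cell_index(points[:, 0], points[:, 1])
    out = np.full(len(points), np.nan)
    out[inside] = layer.values[row[inside], col[inside]]
    n_out = int((~inside).sum())
    if n_out:
        log.warning("sample_at_centroids: %d point(s) outside extent -> NaN", n_out)
    return out


def zonal_mean(layer: GridLayer, zones) -> pd.Series:
    """Mean of cells whose centres fall inside each zone polygon.

    ``zones`` is an iterable of ``(zone_id, Polygon)``.  A zone containing
    no cell centres gets NaN (logged).  Zones are assumed non-overlapping.
    """
    cx, cy = layer.cell_centres()
    flat_x, flat_y = cx.ravel(), cy.ravel()
    vals = np.asarray(layer.values, dtype=float).ravel()
    out = {}
    for zone_id, poly in zones:
        inside = shapely.contains_xy(poly, flat_x, flat_y)
        if not inside.any():
            log.warning("zonal_mean: zone %r contains no cell centres", zone_id)
            out[zone_id] = np.nan
        else:
            out[zone_id] = float(vals[inside].mean())
    return pd.Series(out, name="zonal_mean")


# -- component assembly ---------------------------------------------------

@dataclass
class LandscapeBundle:
    """All raw layers needed to compute the seven components.

    ``landuse`` is a categorical raster whose integer codes index
    ``landuse_codes`` (code 0 = non-relevant "other" area).
    """

    population: GridLayer              # inhabitants per cell (count)
    landuse: GridLayer                 # category codes
    sidewalk: GridLayer                # area fraction per cell
    roads: list                        # [(LineString, road_class), ...]
    transit_points: np.ndarray         # (n, 2) stop/station coordinates
    centroids: pd.DataFrame            # unit_id, x, y
    neighbourhoods: list               # [(zone_id, Polygon), ...]
    landuse_codes: tuple = ("other",) + LANDUSE_CLASSES

    def require(self, name: str):
        layer = getattr(self, name, None)
        if layer is None:
            raise ValueError(f"landscape bundle is missing the {name!r} layer")
        return layer


BUFFER_SCALES = (150.0, 500.0, 1000.0)
NEIGHBOURHOOD_SCALE = "neighbourhood"


def _class_binary(landuse: GridLayer, codes, names) -> GridLayer:
    """Binary fraction raster: 1 where the cell's class is in ``names``."""
    wanted = [codes.index(n) for n in names]
    vals = np.isin(landuse.values, wanted).astype(float)
    return landuse.like(vals, "fraction")


def compute_components(bundle: LandscapeBundle, scale) -> pd.DataFrame:
    """Seven-component table per spatial unit at one scale.

    ``scale`` is a buffer radius in metres (150/500/1000 by convention) or
    the string ``"neighbourhood"``.  Units: population density per hectare,
    point densities per km^2, area components as fractions in [0, 1],
    land-use mix as entropy in [0, 1] computed from scale-aggregated class
    shares.
    """
    pop = bundle.require("population")
    landuse = bundle.require("landuse")
    sidewalk = bundle.require("sidewalk")
    codes = bundle.landuse_codes

    intersections = extract_true_intersections(bundle.require("roads"))
    inter_raster = rasterize_point_count(intersections, pop)
    transit_raster = rasterize_point_count(bundle.require("transit_points"), pop)

    class_rasters = {name: _class_binary(landuse, codes, [name])
                     for name in LANDUSE_CLASSES}
    retail_raster = _class_binary(landuse, codes,
                                  ["commercial", "socio_cultural"])
    green_raster = class_rasters["green_recreation"]

    units = bundle.centroids
    pts = units[["x", "y"]].to_numpy(dtype=float)

    if scale == NEIGHBOURHOOD_SCALE:
        agg = _aggregate_zonal(bundle, pop, retail_raster, green_raster,
                               sidewalk, inter_raster, transit_raster,
                               class_rasters, pts)
    else:
        radius = float(scale)
        agg = _aggregate_focal(pop, retail_raster, green_raster, sidewalk,
                               inter_raster, transit_raster, class_rasters,
                               radius, pts)

    out = pd.DataFrame({"unit_id": units["unit_id"].to_numpy(),
                        "scale": str(scale), **agg})
    return out


def _entropy_from_shares(class_means: dict[str, np.ndarray]) -> np.ndarray:
    stack = np.column_stack([class_means[n] for n in LANDUSE_CLASSES])
    total = stack.sum(axis=1)
    mix = np.zeros(len(stack))
    pos = total > 0
    shares = stack[pos] / total[pos, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(shares > 0, shares * np.log(shares), 0.0)
    mix[pos] = np.clip(-terms.sum(axis=1) / np.log(len(LANDUSE_CLASSES)), 0.0, 1.0)
    n_zero = int((~pos).sum())
    if n_zero:
        log.warning("land-use mix: %d unit(s) with no relevant area scored 0", n_zero)
    return mix


def _aggregate_focal(pop, retail, green, sidewalk, inter, transit,
                     class_rasters, radius, pts):
    pop_km2 = focal_buffer_mean(pop, radius)            # count -> per km^2
    class_means = {n: sample_at_centroids(focal_buffer_mean(r, radius), pts)
                   for n, r in class_rasters.items()}
    return {
        "population_density": sample_at_centroids(pop_km2, pts)
        * (M2_PER_HA / M2_PER_KM2),                     # per km^2 -> per ha
        "retail_service_density": sample_at_centroids(
            focal_buffer_mean(retail, radius), pts),
        "land_use_mix": _entropy_from_shares(class_means),
        "street_connectivity": sample_at_centroids(
            focal_buffer_mean(inter, radius), pts),
        "green_space": class_means["green_recreation"],
        "sidewalk_density": sample_at_centroids(
            focal_buffer_mean(sidewalk, radius), pts),
        "public_transport_density": sample_at_centroids(
            focal_buffer_mean(transit, radius), pts),
    }


def _aggregate_zonal(bundle, pop, retail, green, sidewalk, inter, transit,
                     class_rasters, pts):
    """Per-neighbourhood component values mapped back onto the units."""
    zones = bundle.require("neighbourhoods")
    cell_area_km2 = pop.cell_m ** 2 / M2_PER_KM2
    per_zone = pd.DataFrame({
        "population_density": zonal_mean(pop, zones) / cell_area_km2
        * (M2_PER_HA / M2_PER_KM2),
        "retail_service_density": zonal_mean(retail, zones),
        "green_space": zonal_mean(green, zones),
        "sidewalk_density": zonal_mean(sidewalk, zones),
        "street_connectivity": zonal_mean(inter, zones) / cell_area_km2,
        "public_transport_density": zonal_mean(transit, zones) / cell_area_km2,
    })
    class_means = {n: zonal_mean(r, zones).to_numpy()
                   for n, r in class_rasters.items()}
    per_zone["land_use_mix"] = _entropy_from_shares(class_means)

    # assign each unit its containing neighbourhood's values
    zone_of_unit = np.full(len(pts), -1)
    for k, (zone_id, poly) in enumerate(zones):
        inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
        zone_of_unit[inside] = k
    if (zone_of_unit < 0).any():
        log.warning("%d unit(s) outside every neighbourhood polygon",
                    int((zone_of_unit < 0).sum()))
    out = {}
    zone_rows = per_zone.to_numpy()
    for j, name in enumerate(per_zone.columns):
        col = np.full(len(pts), np.nan)
        ok = zone_of_unit >= 0
        col[ok] = zone_rows[zone_of_unit[ok], j]
        out[name] = col
    return {name: out[name] for name in COMPONENTS}
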