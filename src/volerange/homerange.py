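"""Peeled-core minimum convex polygon (MCP) home ranges.

An animal's home range is the convex hull of its radiotracking fixes. Raw
100%-MCPs are inflated by outlier excursions, so the core home range peels
away the fixes farthest from the harmonic-mean centre down to a stated
inclusion percentage; 75% cores are the field's conventional choice. The
inclusion-curve machinery reproduces the selection procedure: compute mean
MCP area at every inclusion level from 100% down to 25% in 5% steps and find
the knee where outermost fixes stop biasing the estimate.

Geometry is delegated to shapely; polygons are kept in a canonical form
(counter-clockwise, starting from the lexicographically smallest vertex) so
equality is exactly testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint

__all__ = [
    "Polygon",
    "HomeRange",
    "InclusionCurve",
    "convex_hull",
    "polygon_area",
    "harmonic_mean_center",
    "peel_fixes",
    "mcp_core",
    "home_ranges_for_table",
    "core_inclusion_curve",
    "select_core_percentage",
    "home_range_table",
    "PEEL_PERCENTS",
]

#: inclusion levels scanned by the selection procedure, 100 down to 25 by 5
PEEL_PERCENTS = tuple(range(100, 20, -5))

MIN_FIXES_DEFAULT = 28


@dataclass(frozen=True)
class Polygon:
    """A convex polygon in canonical form.

    ``vertices`` are counter-clockwise, implicitly closed, starting from the
    lexicographically smallest (x, y) vertex. Degenerate hulls (a point or a
    segment) are represented with 1 or 2 vertices and area 0.
    """

    vertices: tuple[tuple[float, float], ...]

    @property
    def is_degenerate(self) -> bool:
        return len(self.vertices) < 3

    @property
    def area(self) -> float:
        return polygon_area(self)

    def to_shapely(self) -> shapely.Geometry:
        if len(self.vertices) == 1:
            return shapely.Point(self.vertices[0])
        if len(self.vertices) == 2:
            return shapely.LineString(self.vertices)
        return shapely.Polygon(self.vertices)

    def to_wkt(self) -> str:
        return self.to_shapely().wkt

    def contains(self, x: float, y: float, tol: float = 1e-9) -> bool:
        """Point-in-convex-polygon (boundary inclusive)."""
        v = np.asarray(self.vertices)
        if len(v) == 1:
            return bool(np.hypot(v[0, 0] - x, v[0, 1] - y) <= tol)
        if len(v) == 2:
            return self.to_shapely().distance(shapely.Point(x, y)) <= tol
        a = v
        b = np.roll(v, -1, axis=0)
        cross = (b[:, 0] - a[:, 0]) * (y - a[:, 1]) - \
                (b[:, 1] - a[:, 1]) * (x - a[:, 0])
        return bool(np.all(cross >= -tol))


def _canonicalize(coords: np.ndarray) -> Polygon:
    """Reduce hull coordinates to canonical CCW order, smallest vertex first."""
    pts = [tuple(map(float, p)) for p in coords]
    # drop the repeated closing vertex and duplicates, keeping order
    if len(pts) > 1 and pts[0] == pts[-1]:
        pts = pts[:-1]
    seen: dict[tuple[float, float], None] = {}
    for p in pts:
        seen.setdefault(p, None)
    pts = list(seen)
    if len(pts) >= 3:
        arr = np.asarray(pts)
        area2 = np.sum(arr[:, 0] * np.roll(arr[:, 1], -1)
                       - np.roll(arr[:, 0], -1) * arr[:, 1])
        if area2 < 0:
            pts = pts[::-1]
    start = min(range(len(pts)), key=lambda i: pts[i])
    pts = pts[start:] + pts[:start]
    return Polygon(tuple(pts))


def convex_hull(points) -> Polygon:
    """Convex hull of a point collection, in canonical form.

    Vertices are a subset of the input points; collinear interior boundary
    points are dropped. Degenerate inputs (one point, collinear points)
    yield degenerate polygons.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("convex_hull requires at least one point")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array-like")
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type == "Point":
        return Polygon(((float(hull.x), float(hull.y)),))
    if hull.geom_type == "LineString":
        coords = np.asarray(hull.coords)
        ends = coords[[0, -1]]
        return _canonicalize(ends)
    return _canonicalize(np.asarray(hull.exterior.coords))


def polygon_area(poly: Polygon) -> float:
    """Shoelace area in square metres; degenerate polygons have area 0."""
    v = np.asarray(poly.vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)


def harmonic_mean_center(points, resolution: float = 0.5,
                         pad: float = 1.0,
                         distance_floor: float | None = None
                         ) -> tuple[float, float]:
    """Harmonic-mean centre of a fix cloud.

    Evaluated on a regular grid (``resolution`` metres) over the points'
    bounding box padded by ``pad`` metres; returns the grid point minimising
    the harmonic mean of Euclidean distances to all points. Distances below
    ``distance_floor`` (default: half the grid resolution, the scale below
    which the evaluation grid cannot resolve location anyway) are floored;
    without a floor the sum of inverse distances is dominated by whichever
    grid node happens to fall on a fix and the centre degenerates to the
    nearest-fix node. Ties break to the smallest (y, x).

    The harmonic mean weights nearby fixes heavily, so the centre sits in
    the densest part of the cloud and is robust to outlier excursions.
    """
    pts = np.asarray(points, dtype=float)
    if distance_floor is None:
        distance_floor = resolution / 2.0
    if pts.size == 0:
        raise ValueError("need at least one point")
    if len(pts) == 1:
        return (float(pts[0, 0]), float(pts[0, 1]))
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    gx = np.arange(x0, x1 + resolution / 2, resolution)
    gy = np.arange(y0, y1 + resolution / 2, resolution)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    cand = np.column_stack([xx.ravel(), yy.ravel()])
    d = np.hypot(cand[:, 0:1] - pts[None, :, 0],
                 cand[:, 1:2] - pts[None, :, 1])
    np.maximum(d, distance_floor, out=d)
    inv_sum = np.sum(1.0 / d, axis=1)       # maximise => minimise harmonic mean
    best = inv_sum.max()
    idx = np.flatnonzero(inv_sum >= best * (1 - 1e-12))
    # ties: smallest (y, then x)
    order = np.lexsort((cand[idx, 0], cand[idx, 1]))
    bx, by = cand[idx[order[0]]]
    return (float(bx), float(by))


@dataclass(frozen=True)
class HomeRange:
    """A peeled-core MCP for one animal at a stated inclusion percentage."""

    animal_id: str
    inclusion_percent: int
    n_fixes_total: int
    n_fixes_retained: int
    polygon: Polygon
    area_m2: float
    center: tuple[float, float]
    sufficient_fixes: bool
    degenerate: bool


def peel_fixes(fixes: pd.DataFrame, inclusion_percent: int,
               center: tuple[float, float] | None = None) -> pd.DataFrame:
    """Retain the ``floor(n * percent / 100)`` fixes nearest the
    harmonic-mean centre (computed once from all fixes unless supplied).

    Distance ties break toward the chronologically earlier (day, session)
    fix. Expects columns x_m, y_m and, for tie-breaking, day and session.
    """
    if inclusion_percent not in PEEL_PERCENTS:
        raise ValueError(f"inclusion_percent must be one of {PEEL_PERCENTS}")
    if len(fixes) == 0:
        raise ValueError("no fixes")
    pts = fixes[["x_m", "y_m"]].to_numpy(dtype=float)
    if center is None:
        center = harmonic_mean_center(pts)
    n = len(fixes)
    k = max(int(np.floor(n * inclusion_percent / 100.0)), 1)
    d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    if {"day", "session"}.issubset(fixes.columns):
        sess = fixes["session"].map({"AM": 0, "PM": 1}).fillna(2).to_numpy()
        order = np.lexsort((sess, fixes["day"].to_numpy(), d))
    else:
        order = np.lexsort((np.arange(n), d))
    return fixes.iloc[np.sort(order[:k])]


def mcp_core(fixes: pd.DataFrame, inclusion_percent: int = 75,
             min_fixes: int = MIN_FIXES_DEFAULT,
             animal_id: str | None = None) -> HomeRange:
    """Peel an animal's fixes and build the core MCP.

    The home range is flagged degenerate (area 0) when fewer than three
    distinct fixes remain after peeling; animals below ``min_fixes`` total
    fixes are flagged insufficient but still computed.
    """
    if animal_id is None:
        animal_id = (str(fixes["animal_id"].iloc[0])
                     if "animal_id" in fixes.columns and len(fixes) else "?")
    pts_all = fixes[["x_m", "y_m"]].to_numpy(dtype=float)
    center = harmonic_mean_center(pts_all)
    retained = peel_fixes(fixes, inclusion_percent, center=center)
    pts = retained[["x_m", "y_m"]].to_numpy(dtype=float)
    poly = convex_hull(pts)
    return HomeRange(
        animal_id=animal_id,
        inclusion_percent=inclusion_percent,
        n_fixes_total=len(fixes),
        n_fixes_retained=len(retained),
        polygon=poly,
        area_m2=polygon_area(poly),
        center=center,
        sufficient_fixes=len(fixes) >= min_fixes,
        degenerate=poly.is_degenerate,
    )


def home_ranges_for_table(fixes: pd.DataFrame, inclusion_percent: int = 75,
                          min_fixes: int = MIN_FIXES_DEFAULT
                          ) -> dict[str, HomeRange]:
    """Core home range per animal_id in a fix table."""
    return {
        str(aid): mcp_core(grp, inclusion_percent, min_fixes, animal_id=str(aid))
        for aid, grp in fixes.groupby("animal_id", sort=True)
    }


@dataclass(frozen=True)
class InclusionCurve:
    """Mean core MCP area per inclusion percentage, over qualifying animals."""

    percents: tuple[int, ...]
    mean_areas: tuple[float, ...]
    n_animals: int
    per_animal: dict[str, tuple[float, ...]]


def core_inclusion_curve(fixes: pd.DataFrame,
                         min_fixes: int = MIN_FIXES_DEFAULT
                         ) -> InclusionCurve:
    """Average peeled-MCP area at each inclusion level 100 -> 25 by 5.

    Animals with fewer than ``min_fixes`` fixes are excluded from the curve
    (their home ranges are still computable individually). The per-animal
    centre is computed once from all fixes and reused across peels, so each
    animal's area profile is non-increasing as the inclusion level drops.
    """
    per_animal: dict[str, tuple[float, ...]] = {}
    for aid, grp in fixes.groupby("animal_id", sort=True):
        if len(grp) < min_fixes:
            continue
        pts = grp[["x_m", "y_m"]].to_numpy(dtype=float)
        center = harmonic_mean_center(pts)
        areas = []
        for p in PEEL_PERCENTS:
            retained = peel_fixes(grp, p, center=center)
            areas.append(polygon_area(
                convex_hull(retained[["x_m", "y_m"]].to_numpy(dtype=float))))
        per_animal[str(aid)] = tuple(areas)
    if not per_animal:
        raise ValueError(f"no animal has >= {min_fixes} fixes")
    mat = np.asarray(list(per_animal.values()))
    return InclusionCurve(percents=PEEL_PERCENTS,
                          mean_areas=tuple(mat.mean(axis=0)),
                          n_animals=len(per_animal),
                          per_animal=per_animal)


def select_core_percentage(curve: InclusionCurve,
                           method: str = "knee",
                           lo: int = 30, hi: int = 95,
                           pin: int | None = None) -> int:
    """Operationalise the visual choice of the core inclusion level.

    The field procedure plots mean MCP area against inclusion percentage and
    reads off the knee where the outermost fixes stop inflating the
    estimate. Two operationalisations are provided:

    - ``"knee"`` (default): the interior percentage whose point on the curve
      lies farthest below the chord joining the curve's endpoints (the
      standard maximum-distance-to-chord knee detector; areas are scaled to
      the chord so the answer is unit-free).
    - ``"second_difference"``: the percentage maximising the discrete second
      difference of mean area.

    The answer is constrained to [``lo``, ``hi``]. ``pin`` overrides the
    procedure entirely; a flat curve returns 75 (the conventional core) with
    a warning.
    """
    if pin is not None:
        return int(pin)
    p = np.asarray(curve.percents, dtype=float)       # 100 -> 25
    a = np.asarray(curve.mean_areas, dtype=float)
    if np.ptp(a) <= 1e-12:
        warnings.warn("flat inclusion curve; falling back to the "
                      "conventional 75% core", stacklevel=2)
        return 75
    sel = (p >= lo) & (p <= hi)
    if method == "second_difference":
        d2 = a[:-2] - 2.0 * a[1:-1] + a[2:]
        interior = sel[1:-1]
        cand = np.where(interior, d2, -np.inf)
        i = int(np.argmax(cand)) + 1
        return int(p[i])
    if method == "knee":
        # normalise both axes, measure vertical gap below the end-to-end chord
        x = (p - p.min()) / np.ptp(p)
        y = (a - a.min()) / np.ptp(a)
        chord = y[0] + (x - x[0]) * (y[-1] - y[0]) / (x[-1] - x[0])
        gap = chord - y
        cand = np.where(sel, gap, -np.inf)
        return int(p[int(np.argmax(cand))])
    raise ValueError(f"unknown method {method!r}")


def home_range_table(ranges: dict[str, HomeRange]) -> pd.DataFrame:
    """Tidy per-animal table of the computed cores."""
    return pd.DataFrame([{
        "animal_id": hr.animal_id,
        "inclusion_percent": hr.inclusion_percent,
        "n_fixes_total": hr.n_fixes_total,
        "n_fixes_retained": hr.n_fixes_retained,
        "area_m2": hr.area_m2,
        "center_x": hr.center[0],
        "center_y": hr.center[1],
        "sufficient_fixes": hr.sufficient_fixes,
        "degenerate": hr.degenerate,
    } for hr in ranges.values()]).sort_values("animal_id",
                                              ignore_index=True)
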