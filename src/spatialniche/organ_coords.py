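"""Organ polar coordinate system: boundary estimation, depth/angle transform,
depth-binned composition profiles.

The organ frame places a user-chosen origin (for the kidney: a centre point
in the papilla) inside the estimated outer tissue boundary. Each cell is then
described by its *depth* — 0 at the capsule (boundary), 1 at the origin — and
its *angle*, the inclination of the cell relative to the origin's positive
x-axis. Depth is computed along the origin→cell ray: with b the first
boundary intersection of that ray, depth = |p − b| / |o − b|, which ties the
normalising boundary distance to the same boundary point and keeps depth in
[0, 1] by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon, mapping, shape
from shapely.ops import unary_union


class GeometryError(ValueError):
    """Degenerate geometry: collinear points, origin outside boundary, ..."""


@dataclass
class Circle:
    """Exact circular boundary (centre, radius) in micrometres.

    Used where the boundary is known analytically (synthetic tissues,
    idealised checks): the ray–boundary intersection is then solved in
    closed form instead of against a polygonal approximation, so depth is
    exact to floating-point precision.
    """

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError("circle radius must be positive")

    def contains_point(self, xy) -> bool:
        return float(np.hypot(xy[0] - self.center[0], xy[1] - self.center[1])) < self.radius

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        (cx, cy), r = self.center, self.radius
        return (cx - r, cy - r, cx + r, cy + r)

    def to_polygon(self, quad_segs: int = 256) -> Polygon:
        return Polygon(shapely.Point(self.center).buffer(self.radius,
                                                         quad_segs=quad_segs).exterior)


# ---------------------------------------------------------------------------
# boundary estimation (alpha shape)
# ---------------------------------------------------------------------------

def estimate_boundary(points: np.ndarray, alpha: float | None = None) -> Polygon:
    """Estimate the outer tissue boundary of a point cloud as an alpha shape.

    Parameters
    ----------
    points
        (N, 2) positions in micrometres; at least 3 non-collinear points.
    alpha
        Length scale: Delaunay triangles with circumradius <= alpha are kept
        and their union's outer ring is the boundary. ``alpha=inf`` (or
        ``None`` with no finite default applicable) reduces to the convex
        hull. Default: 3x the median nearest-neighbour spacing, which adapts
        to the sampling density.

    Returns
    -------
    shapely Polygon (single outer ring; holes are discarded).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise GeometryError("need at least 3 two-dimensional points")
    pts = np.unique(pts, axis=0)
    if len(pts) < 3:
        raise GeometryError("need at least 3 distinct points")

    if alpha is None:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(pts, k=2)
        alpha = 3.0 * float(np.median(d[:, 1]))

    try:
        tri = Delaunay(pts)
    except Exception as exc:  # QhullError on collinear input
        raise GeometryError(f"degenerate point configuration: {exc}") from exc

    simplices = tri.simplices
    a, b, c = (pts[simplices[:, i]] for i in range(3))
    # circumradius = abc / (4 * area)
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    ab, ac = b - a, c - a
    area2 = np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])  # 2 * triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        circum_r = (la * lb * lc) / (2.0 * area2)
    keep = np.isfinite(circum_r) & (circum_r <= alpha) if np.isfinite(alpha) \
        else np.full(len(simplices), True)
    keep &= area2 > 0

    if not keep.any():
        raise GeometryError("alpha too small: no triangle survives")
    union = unary_union([Polygon(pts[s]) for s in simplices[keep]])
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda g: g.area)
    ring = Polygon(union.exterior)
    if not ring.is_valid or ring.area == 0:
        raise GeometryError("boundary estimation produced a degenerate polygon")
    return ring


# ---------------------------------------------------------------------------
# organ frame and the depth/angle transform
# ---------------------------------------------------------------------------

@dataclass
class OrganFrame:
    """Outer tissue boundary plus the user-chosen origin of the organ frame.

    The origin must lie strictly inside the boundary; it is always supplied
    by the caller (``suggest_origin`` can propose one, but nothing is chosen
    silently).
    """

    boundary: Polygon | Circle
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        if isinstance(self.boundary, Circle):
            if not self.boundary.contains_point(self.origin):
                raise GeometryError("origin must lie strictly inside the boundary")
            return
        if not self.boundary.is_valid or not self.boundary.is_simple:
            raise GeometryError("boundary polygon must be simple and valid")
        if not self.boundary.contains(shapely.points(np.asarray(self.origin, float))):
            raise GeometryError("origin must lie strictly inside the boundary")

    def to_geojson(self, path) -> None:
        props: dict = {"origin": list(map(float, self.origin))}
        if isinstance(self.boundary, Circle):
            props["circle"] = {"center": list(map(float, self.boundary.center)),
                               "radius": float(self.boundary.radius)}
            geometry = mapping(self.boundary.to_polygon())
        else:
            geometry = mapping(self.boundary)
        payload = {"type": "Feature", "properties": props, "geometry": geometry}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_geojson(cls, path) -> "OrganFrame":
        with open(path) as fh:
            data = json.load(fh)
        props = data["properties"]
        if "circle" in props:
            boundary: Polygon | Circle = Circle(tuple(props["circle"]["center"]),
                                                props["circle"]["radius"])
        else:
            boundary = Polygon(shape(data["geometry"]).exterior)
        return cls(boundary, tuple(props["origin"]))


def suggest_origin(cells: pd.DataFrame, type_label: str) -> tuple[float, float]:
    """Centroid of a named cell type (e.g. urothelium) as an origin proposal."""
    sel = cells.loc[cells["type_label"] == type_label]
    if sel.empty:
        raise ValueError(f"no cells with type label {type_label!r}")
    return float(sel["x"].mean()), float(sel["y"].mean())


def organ_transform(
    points: np.ndarray, frame: OrganFrame
) -> pd.DataFrame:
    """Transform Cartesian positions into (depth, angle) organ coordinates.

    For each point p: cast the ray origin→p, find its first boundary
    intersection b, and set depth = |p − b| / |o − b| and angle = atan2 of
    p − o (radians in (−π, π]). Conventions: a point exactly at the origin
    has depth 1 and angle 0; points outside the boundary are clamped to
    depth 0 and flagged in the ``outside`` column (their count is also
    reported via a warning).
    """
    pts = np.asarray(points, float)
    if pts.ndim == 1:
        pts = pts[None, :]
    o = np.asarray(frame.origin, float)
    vec = pts - o
    r = np.hypot(vec[:, 0], vec[:, 1])
    angle = np.where(r > 0, np.arctan2(vec[:, 1], vec[:, 0]), 0.0)

    if isinstance(frame.boundary, Circle):
        # closed-form ray/circle intersection: |o + t u − c|² = R², t > 0
        c = np.asarray(frame.boundary.center, float)
        R = frame.boundary.radius
        with np.errstate(invalid="ignore"):
            u = np.where(r[:, None] > 0, vec / np.maximum(r, 1e-300)[:, None], 0.0)
        oc = o - c
        bq = u @ oc
        cq = float(oc @ oc) - R * R    # negative: origin strictly inside
        t = -bq + np.sqrt(bq * bq - cq)
        depth = np.where(r > 0, (t - r) / np.where(t > 0, t, 1.0), 1.0)
        outside = depth < 0
        n_out = int(outside.sum())
        if n_out:
            warnings.warn(f"{n_out} point(s) outside the boundary clamped to depth 0",
                          stacklevel=2)
        return pd.DataFrame({"depth": np.clip(depth, 0.0, 1.0),
                             "angle": angle, "outside": outside})

    # far length: any ray of this length from the origin exits the polygon
    minx, miny, maxx, maxy = frame.boundary.bounds
    far = 2.0 * max(maxx - minx, maxy - miny) + 1.0

    ring = shapely.LineString(frame.boundary.exterior.coords)
    depth = np.ones(len(pts))
    boundary_dist = np.full(len(pts), np.nan)
    at_origin = r == 0
    for i in np.where(~at_origin)[0]:
        direction = vec[i] / r[i]
        ray = shapely.LineString([o, o + far * direction])
        hit = ring.intersection(ray)
        if hit.is_empty:  # origin inside => cannot happen, defensive
            raise GeometryError("origin ray does not intersect the boundary")
        cands = (
            [hit] if hit.geom_type == "Point"
            else [g for g in getattr(hit, "geoms", [hit])]
        )
        # first intersection along the ray = smallest distance from origin
        dists = []
        for g in cands:
            coords = np.asarray(g.coords) if g.geom_type != "Point" \
                else np.asarray(g.coords)
            dists.append(np.min(np.hypot(coords[:, 0] - o[0], coords[:, 1] - o[1])))
        d_ob = float(min(dists))
        boundary_dist[i] = d_ob
        depth[i] = (d_ob - r[i]) / d_ob

    outside = depth < 0
    n_outside = int(outside.sum())
    if n_outside:
        warnings.warn(f"{n_outside} point(s) outside the boundary clamped to depth 0",
                      stacklevel=2)
    depth = np.clip(depth, 0.0, 1.0)
    return pd.DataFrame({
        "depth": depth,
        "angle": angle,
        "outside": outside,
    })


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Per-depth-bin counts and within-bin proportions per category."""

    bin_edges: np.ndarray          # (n_bins + 1,) over [0, 1]
    counts: pd.DataFrame           # bins x categories
    proportions: pd.DataFrame      # bins x categories; NaN rows for empty bins

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


def depth_profile(
    depths: np.ndarray,
    categories: np.ndarray,
    n_bins: int = 10,
) -> DepthProfile:
    """Bin observations by depth and tabulate category composition per bin.

    Bins are equal-width over [0, 1]; the last bin is closed at 1. Empty bins
    get zero counts and NaN proportions (reported as empty, never propagated
    into neighbouring bins). Within a non-empty bin, proportions over
    categories sum to 1.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    depths = np.asarray(depths, float)
    categories = np.asarray(categories)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(depths, edges[1:-1]), 0, n_bins - 1)
    df = pd.DataFrame({"bin": idx, "category": categories})
    counts = (
        df.groupby(["bin", "category"], observed=True).size().unstack(fill_value=0)
        .reindex(range(n_bins), fill_value=0)
    )
    counts.index = pd.Index(range(1, n_bins + 1), name="bin")
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = counts.div(totals, axis=0)
    proportions[totals == 0] = np.nan
    return DepthProfile(edges, counts, proportions)
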