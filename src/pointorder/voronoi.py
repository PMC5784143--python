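"""Window-clipped Voronoi tessellation and the entropic order metrics
derived from it.

The tessellation partitions the observation window into one convex cell
per particle.  Clipping is implemented by the mirror trick: the pattern
is reflected across each of the four window edges before tessellating,
so every real particle's region is finite and the clipped cells tile
the window exactly — the sum of cell areas equals the window area to
machine precision, which is the invariant all downstream density
metrics rely on.

From the cells follow the local metrics:

* coordination number — the count of retained cell facets (geometric
  neighbours);
* local hexagonal radius — ``r_hex = sqrt(A_vor) * (2*sqrt(3))**-0.5``,
  the radius whose regular-hexagon cell has the observed area;
* the lattice disorder parameter ``delta_r`` — the spread of ``r_hex``
  over interior cells, reported both as the direct standard deviation
  of ``r_hex`` and via first-order error propagation from the cell-area
  standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import LineString, Polygon, box

from .pattern import ObservationWindow, PointPattern

__all__ = [
    "VoronoiCell",
    "VoronoiPartition",
    "DisorderEstimate",
    "tessellate",
    "coordination",
    "coordination_histogram",
    "local_hex_radius",
    "disorder_estimate",
    "global_density_metrics",
]

_HEX_AREA_FACTOR = 2.0 * np.sqrt(3.0)  # area of a regular hexagon of apothem-radius 1


@dataclass
class VoronoiCell:
    particle_index: int
    polygon: np.ndarray  # (k, 2) clipped vertices, counter-clockwise
    area: float
    facets: dict[int, float] = field(default_factory=dict)  # neighbour -> facet length
    is_edge: bool = False

    @property
    def coordination(self) -> int:
        return len(self.facets)


@dataclass
class VoronoiPartition:
    cells: list[VoronoiCell]
    window: ObservationWindow
    facet_epsilon: float
    points: np.ndarray | None = None  # generator coordinates, (N, 2)

    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.cells])

    @property
    def edge_mask(self) -> np.ndarray:
        return np.array([c.is_edge for c in self.cells], dtype=bool)

    def interior_cells(self) -> list[VoronoiCell]:
        return [c for c in self.cells if not c.is_edge]


def tessellate(
    pattern: PointPattern, facet_epsilon: float | None = None
) -> VoronoiPartition:
    """Window-clipped Voronoi tessellation of a point pattern.

    Facets shorter than ``facet_epsilon`` (default ``1e-6`` of the window
    diagonal) are treated as degenerate point contacts: the facet and its
    mirror-image twin are dropped symmetrically, so e.g. the four cells
    meeting at a vertex of a perfect square lattice contribute
    coordination 4, not 6–8.

    Raises on fewer than two points or (near-)coincident generators, for
    which the tessellation is undefined.
    """
    pts = pattern.points
    n = pattern.n
    if n < 2:
        raise ValueError("tessellation needs at least 2 points")
    diag = pattern.window.diagonal
    # coincident generators make the tessellation ill-defined
    dists, idx = cKDTree(pts).query(pts, k=2)
    if np.min(dists[:, 1]) < 1e-12 * diag:
        raise ValueError("duplicate (coincident) points in pattern")
    if facet_epsilon is None:
        facet_epsilon = 1e-6 * diag

    w = pattern.window
    # Reflection lines sit a hair outside the window so a point lying
    # exactly on the boundary never coincides with its own mirror.
    delta = 1e-9 * diag
    mirrors = []
    for axis, line, sign in (
        (0, w.x_min - delta, -1),
        (0, w.x_max + delta, +1),
        (1, w.y_min - delta, -1),
        (1, w.y_max + delta, +1),
    ):
        m = pts.copy()
        m[:, axis] = 2.0 * line - m[:, axis]
        mirrors.append(m)
    all_pts = np.vstack([pts] + mirrors)

    vor = Voronoi(all_pts)
    clip_box = box(w.x_min, w.y_min, w.x_max, w.y_max)

    cells: list[VoronoiCell] = []
    boundary_tol = 1e-7 * diag
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # pragma: no cover - mirror trick guards
            raise RuntimeError(f"unbounded Voronoi region for particle {i}")
        verts = vor.vertices[region]
        # angular sort about the generator: cells are convex
        ang = np.arctan2(verts[:, 1] - pts[i, 1], verts[:, 0] - pts[i, 0])
        verts = verts[np.argsort(ang)]
        poly = Polygon(verts)
        if not poly.is_valid:  # pragma: no cover - safety net
            poly = poly.buffer(0)
        clipped = poly.intersection(clip_box)
        if clipped.is_empty or clipped.area <= 0:  # pragma: no cover
            raise RuntimeError(f"empty clipped cell for particle {i}")
        xy = np.asarray(clipped.exterior.coords)[:-1]
        on_boundary = bool(
            np.any(
                (np.abs(xy[:, 0] - w.x_min) < boundary_tol)
                | (np.abs(xy[:, 0] - w.x_max) < boundary_tol)
                | (np.abs(xy[:, 1] - w.y_min) < boundary_tol)
                | (np.abs(xy[:, 1] - w.y_max) < boundary_tol)
            )
        )
        cells.append(
            VoronoiCell(
                particle_index=i,
                polygon=xy,
                area=float(clipped.area),
                is_edge=on_boundary,
            )
        )

    # facets between pairs of real particles, clipped to the window
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n or q >= n:
            continue
        if -1 in rv:  # pragma: no cover - real-point ridges are finite
            continue
        seg = LineString(vor.vertices[list(rv)])
        length = seg.intersection(clip_box).length
        if length > facet_epsilon:
            cells[p].facets[q] = float(length)
            cells[q].facets[p] = float(length)

    return VoronoiPartition(
        cells=cells, window=w, facet_epsilon=float(facet_epsilon), points=pts.copy()
    )


def coordination(partition: VoronoiPartition, exclude_edge: bool = False) -> np.ndarray:
    """Per-particle coordination numbers (retained facet counts).

    With ``exclude_edge`` the array covers interior particles only, in
    particle order; edge cells have truncated facet sets, so excluding
    them is the default for all summary statistics elsewhere.
    """
    cells = partition.interior_cells() if exclude_edge else partition.cells
    return np.array([c.coordination for c in cells], dtype=int)


def coordination_histogram(
    partition: VoronoiPartition, exclude_edge: bool = True
) -> dict[int, float]:
    """Probability of each coordination number; values sum to 1."""
    counts = coordination(partition, exclude_edge=exclude_edge)
    if counts.size == 0:
        return {}
    vals, freq = np.unique(counts, return_counts=True)
    total = freq.sum()
    return {int(v): float(f) / total for v, f in zip(vals, freq)}


def local_hex_radius(area):
    """Radius of the regular hexagon (apothem convention) whose cell area
    equals ``area``: ``r_hex = sqrt(area) * (2*sqrt(3))**-0.5``."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("cell area must be positive")
    r = np.sqrt(area) / np.sqrt(_HEX_AREA_FACTOR)
    return float(r) if r.ndim == 0 else r


@dataclass
class DisorderEstimate:
    """Lattice disorder summary from interior Voronoi cell areas.

    ``delta_r_variance`` (the standard deviation of the local hexagonal
    radii) is the canonical value; ``delta_r_propagated`` carries the
    first-order error-propagation estimate
    ``|d r_hex / d A| * std(A)`` evaluated at the mean interior area.
    Both vanish for a perfect lattice.
    """

    mean_spacing: float
    delta_r_propagated: float
    delta_r_variance: float
    area_std: float
    n_interior: int


def disorder_estimate(partition: VoronoiPartition) -> DisorderEstimate:
    """Estimate the mean local spacing and the lattice disorder parameter.

    Only interior (non-edge) cells enter: edge cells are clipped by the
    window and would bias the local density.  Requires at least three
    interior cells.
    """
    areas = np.array([c.area for c in partition.interior_cells()])
    if areas.size < 3:
        raise ValueError(
            f"need >= 3 interior cells for a disorder estimate, have {areas.size}"
        )
    r_hex = local_hex_radius(areas)
    mean_spacing = float(np.mean(2.0 * r_hex))
    area_std = float(np.std(areas, ddof=1))
    mean_area = float(np.mean(areas))
    # d r_hex / d A = 1/2 * A**-1/2 * (2 sqrt 3)**-1/2, at the mean area
    deriv = 0.5 / np.sqrt(mean_area * _HEX_AREA_FACTOR)
    return DisorderEstimate(
        mean_spacing=mean_spacing,
        delta_r_propagated=float(deriv * area_std),
        delta_r_variance=float(np.std(r_hex, ddof=1)),
        area_std=area_std,
        n_interior=int(areas.size),
    )


def global_density_metrics(pattern: PointPattern) -> dict:
    """Global observables: N, intensity, and (with radii) the mean object
    radius and covering fraction ``phi = sum(pi r^2) / A_box`` (overlap
    not corrected)."""
    out = {"N": pattern.n, "lambda": pattern.intensity}
    if pattern.radii is not None:
        out["mean_radius"] = float(np.mean(pattern.radii))
        out["covering_fraction"] = float(
            np.sum(np.pi * pattern.radii**2) / pattern.window.area
        )
    return out
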