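"""Core domain types: the observation window and the point pattern.

Every analysis in this package starts from a :class:`PointPattern` — an
ordered set of 2D centroid coordinates inside a bounded rectangular
observation window.  The window matters as much as the points: the
intensity ``lambda = N / area`` that normalizes the pair correlation
function and sets reference lattice spacings is defined with respect to
the window actually observed, not the convex hull of the points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ObservationWindow", "PointPattern"]


@dataclass(frozen=True)
class ObservationWindow:
    """Axis-aligned rectangular observation window.

    Coordinates follow the mathematical convention: origin at the lower
    left, y increasing upward.  Units are whatever the pattern carries
    (nm, µm or px) — the window never converts units.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate window: [{self.x_min}, {self.x_max}] x "
                f"[{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    @property
    def centre(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def contains(self, points: np.ndarray, atol: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside or on the boundary (± ``atol``)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return (
            (pts[:, 0] >= self.x_min - atol)
            & (pts[:, 0] <= self.x_max + atol)
            & (pts[:, 1] >= self.y_min - atol)
            & (pts[:, 1] <= self.y_max + atol)
        )

    @classmethod
    def bounding(cls, points: np.ndarray) -> "ObservationWindow":
        """Tight axis-aligned bounding box of a point set.

        Degenerate (collinear) extents are padded by a tiny margin so the
        window always has positive area.
        """
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        x_min, y_min = pts.min(axis=0)
        x_max, y_max = pts.max(axis=0)
        span = max(x_max - x_min, y_max - y_min, 1.0)
        eps = 1e-9 * span
        if x_max - x_min <= 0:
            x_min, x_max = x_min - 0.5 * span * 1e-6 - eps, x_max + 0.5 * span * 1e-6 + eps
        if y_max - y_min <= 0:
            y_min, y_max = y_min - 0.5 * span * 1e-6 - eps, y_max + 0.5 * span * 1e-6 + eps
        return cls(x_min, y_min, x_max, y_max)

    def as_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "y_min": self.y_min,
            "x_max": self.x_max,
            "y_max": self.y_max,
        }


@dataclass
class PointPattern:
    """Centroids of objects observed in a bounded 2D window.

    Parameters
    ----------
    points
        ``(N, 2)`` array of ``(x, y)`` coordinates, all in one length unit.
    window
        The observation window; every point must lie inside or on it.
    pixel_size
        Physical length of one pixel, if coordinates were converted from
        pixels at ingestion (recorded for provenance only).
    radii
        Optional per-object radius, same unit as the coordinates; enables
        the covering-fraction metric.
    label
        Free-text sample identifier.
    """

    points: np.ndarray
    window: ObservationWindow
    pixel_size: float | None = None
    radii: np.ndarray | None = None
    label: str = ""
    unit: str = "au"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (N, 2)")
        if self.points.shape[0] < 1:
            raise ValueError("no points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates")
        tol = 1e-9 * self.window.diagonal
        if not np.all(self.window.contains(self.points, atol=tol)):
            outside = int((~self.window.contains(self.points, atol=tol)).sum())
            raise ValueError(f"{outside} point(s) outside the observation window")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
            if self.radii.shape[0] != self.points.shape[0]:
                raise ValueError("radii length must match number of points")

    @property
    def n(self) -> int:
        """Number of points N."""
        return int(self.points.shape[0])

    @property
    def intensity(self) -> float:
        """Points per unit window area, lambda = N / A_box."""
        return self.n / self.window.area

    def translated(self, dx: float, dy: float) -> "PointPattern":
        """Rigidly translate pattern and window together."""
        w = self.window
        return PointPattern(
            self.points + np.array([dx, dy]),
            ObservationWindow(w.x_min + dx, w.y_min + dy, w.x_max + dx, w.y_max + dy),
            pixel_size=self.pixel_size,
            radii=None if self.radii is None else self.radii.copy(),
            label=self.label,
            unit=self.unit,
        )

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PointPattern(n={self.n}, window=[{self.window.x_min:g}, "
            f"{self.window.x_max:g}]x[{self.window.y_min:g}, {self.window.y_max:g}], "
            f"unit={self.unit!r}, label={self.label!r})"
        )
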