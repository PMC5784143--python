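"""Synthetic reference patterns: ideal lattices, hexatic ensembles, CSR,
and a confined-packing fixture.

The reference lattices are matched to a target *intensity* (points per
unit area) rather than to an explicit spacing, mirroring how a reference
is constructed for an experimental micrograph: the observed ``N`` and
window area fix ``lambda = N / A_box`` and hence the lattice spacing.
For the triangular ("hexagonal") lattice the nearest-neighbour spacing
follows from equating the hexagonal Voronoi cell area to ``1/lambda``:

    2 r_hex = (2 / (lambda * sqrt(3)))**0.5

A *hexatic* ensemble applies independent isotropic Gaussian displacements
of scale ``delta_r`` (per-axis standard deviation) to every lattice site,
producing a tunable reference between crystal and liquid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pattern import ObservationWindow, PointPattern

__all__ = [
    "hexagonal_spacing",
    "hexagonal_lattice",
    "square_lattice",
    "HexaticSpec",
    "hexatic_ensemble",
    "csr",
    "confined_packing",
]


def hexagonal_spacing(intensity: float) -> float:
    """Nearest-neighbour spacing 2*r_hex of a triangular lattice with the
    given intensity: ``(2 / (intensity * sqrt(3)))**0.5``."""
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    return float(np.sqrt(2.0 / (intensity * np.sqrt(3.0))))


def _crop(points: np.ndarray, window: ObservationWindow) -> np.ndarray:
    tol = 1e-9 * window.diagonal
    pts = points[window.contains(points, atol=tol)]
    return np.clip(
        pts,
        [window.x_min, window.y_min],
        [window.x_max, window.y_max],
    )


def hexagonal_lattice(intensity: float, window: ObservationWindow) -> PointPattern:
    """Triangular lattice of the given intensity, cropped to the window.

    Sites are generated on an extended grid anchored so that the window
    centre is a lattice site; the pattern is therefore stable under
    window resizing.
    """
    a = hexagonal_spacing(intensity)
    row_h = a * np.sqrt(3.0) / 2.0
    cx, cy = window.centre
    n_cols = int(np.ceil(window.width / a)) + 2
    n_rows = int(np.ceil(window.height / row_h)) + 2
    cols = np.arange(-n_cols, n_cols + 1)
    rows = np.arange(-n_rows, n_rows + 1)
    jj, ii = np.meshgrid(rows, cols, indexing="ij")
    x = cx + ii * a + (jj % 2) * (a / 2.0)
    y = cy + jj * row_h
    pts = _crop(np.column_stack([x.ravel(), y.ravel()]), window)
    if pts.shape[0] < 1:
        raise ValueError("window too small to hold a single lattice site")
    return PointPattern(pts, window, label=f"hexagonal(lambda={intensity:g})")


def square_lattice(intensity: float, window: ObservationWindow) -> PointPattern:
    """Square lattice with spacing ``intensity**-0.5``, cropped to the window."""
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    a = 1.0 / np.sqrt(intensity)
    cx, cy = window.centre
    n_cols = int(np.ceil(window.width / a)) + 2
    n_rows = int(np.ceil(window.height / a)) + 2
    ii, jj = np.meshgrid(
        np.arange(-n_cols, n_cols + 1), np.arange(-n_rows, n_rows + 1), indexing="ij"
    )
    pts = _crop(
        np.column_stack([(cx + ii * a).ravel(), (cy + jj * a).ravel()]), window
    )
    if pts.shape[0] < 1:
        raise ValueError("window too small to hold a single lattice site")
    return PointPattern(pts, window, label=f"square(lambda={intensity:g})")


@dataclass
class HexaticSpec:
    """Specification of a Gaussian-displaced lattice ensemble.

    ``delta_r`` is the per-axis standard deviation of the independent
    Gaussian displacement applied to each site in each realization.
    """

    base_lattice: PointPattern
    delta_r: float
    n_realizations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_r < 0:
            raise ValueError("delta_r must be non-negative")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


def hexatic_ensemble(spec: HexaticSpec) -> list[PointPattern]:
    """Generate ``n_realizations`` independently shaken copies of the base
    pattern.

    Displacements are always drawn about the *base* positions, never
    chained from the previous realization.  Displaced points that would
    leave the window are clamped to the boundary so every realization
    shares the base window.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.base_lattice
    w = base.window
    lo = np.array([w.x_min, w.y_min])
    hi = np.array([w.x_max, w.y_max])
    out: list[PointPattern] = []
    for k in range(spec.n_realizations):
        if spec.delta_r == 0:
            pts = base.points.copy()
        else:
            pts = base.points + rng.normal(0.0, spec.delta_r, size=base.points.shape)
            pts = np.clip(pts, lo, hi)
        out.append(
            PointPattern(pts, w, label=f"{base.label}+jitter({spec.delta_r:g})#{k}",
                         unit=base.unit)
        )
    return out


def csr(intensity: float, window: ObservationWindow, seed: int) -> PointPattern:
    """Complete spatial randomness: a homogeneous Poisson process.

    ``N`` is drawn Poisson(intensity * area); positions are uniform in
    the window.  Fully determined by the seed.
    """
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(intensity * window.area))
    n = max(n, 1)
    pts = np.column_stack(
        [
            rng.uniform(window.x_min, window.x_max, n),
            rng.uniform(window.y_min, window.y_max, n),
        ]
    )
    return PointPattern(pts, window, label=f"csr(lambda={intensity:g})")


def _relax(
    pts: np.ndarray,
    window: ObservationWindow,
    spacing: float,
    n_iter: int,
    step: float,
) -> tuple[np.ndarray, bool]:
    """Iterative short-range soft repulsion with hard-wall clamping."""
    lo = np.array([window.x_min, window.y_min])
    hi = np.array([window.x_max, window.y_max])
    cutoff = 1.6 * spacing
    for _ in range(n_iter):
        tree = cKDTree(pts)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        force = np.zeros_like(pts)
        max_move = 0.0
        if len(pairs):
            d = pts[pairs[:, 0]] - pts[pairs[:, 1]]
            dist = np.maximum(np.linalg.norm(d, axis=1), 1e-12 * spacing)
            mag = (cutoff - dist) / cutoff  # linear soft repulsion
            f = d * (mag / dist)[:, None]
            np.add.at(force, pairs[:, 0], f)
            np.add.at(force, pairs[:, 1], -f)
            move = step * spacing * force
            max_move = float(np.abs(move).max())
            pts = pts + move
        pts = np.clip(pts, lo, hi)
        if max_move < 1e-4 * spacing:
            return pts, True
    return pts, False


def _wall_frame_sites(window: ObservationWindow, s: float) -> np.ndarray:
    """Two hexagonally stacked rectangular rings of sites hugging the walls."""
    rings = []
    for ring, (offset, stagger) in enumerate(
        [(0.5 * s, 0.0), (0.5 * s + 0.5 * np.sqrt(3.0) * s, 0.5)]
    ):
        x0, x1 = window.x_min + offset, window.x_max - offset
        y0, y1 = window.y_min + offset, window.y_max - offset
        nx = max(int(np.floor((x1 - x0) / s)), 1)
        ny = max(int(np.floor((y1 - y0) / s)), 1)
        sx, sy = (x1 - x0) / nx, (y1 - y0) / ny
        xs = x0 + (np.arange(nx) + stagger) * sx
        ys = y0 + (np.arange(1, ny) + stagger) * sy
        rings.append(np.column_stack([xs, np.full(xs.size, y0)]))
        rings.append(np.column_stack([xs + (sx if ring else 0), np.full(xs.size, y1)]))
        rings.append(np.column_stack([np.full(ys.size, x0), ys]))
        rings.append(np.column_stack([np.full(ys.size, x1), ys]))
    return np.vstack(rings)


def confined_packing(
    n: int,
    window: ObservationWindow,
    seed: int,
    *,
    n_iter: int = 60,
    step: float = 0.05,
) -> PointPattern:
    """Fixture emulating repulsive particles confined by hard walls.

    The construction seeds the morphology square confinement produces —
    hexagonally stacked rows hugging the walls with a sterically
    frustrated square-packed core — and then smooths the seams with a
    short iterative soft-repulsion relaxation against the hard walls.
    For small ``n`` (below ~60, where wall bands make no sense) the
    points relax from a jittered grid under pure repulsion, which drives
    the minimal cases toward the near-corner symmetric arrangement.

    Deterministic under the seed; purely qualitative — no thermodynamic
    claim is made.  Non-convergence of the smoothing pass is silent by
    design (the construction, not the relaxation, carries the
    morphology); the pure-repulsion small-``n`` path warns if it fails
    to converge.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    rng = np.random.default_rng(seed)
    spacing = np.sqrt(window.area / n)

    if n < 60:
        m = int(np.ceil(np.sqrt(n)))
        gx = window.x_min + (np.arange(m) + 0.5) * window.width / m
        gy = window.y_min + (np.arange(m) + 0.5) * window.height / m
        grid = np.array([(x, y) for y in gy for x in gx])[:n]
        pts = grid + rng.normal(0.0, 0.02 * spacing, size=(n, 2))
        pts, converged = _relax(pts, window, spacing, 400, 0.08)
        if not converged:
            warnings.warn(
                "confined_packing: relaxation not fully converged", RuntimeWarning
            )
        return PointPattern(pts, window, label=f"confined(n={n})")

    frame = _wall_frame_sites(window, spacing)
    inset = (0.5 + np.sqrt(3.0)) * spacing
    core_lo = np.array([window.x_min + inset, window.y_min + inset])
    core_hi = np.array([window.x_max - inset, window.y_max - inset])
    n_core = n - frame.shape[0]
    if n_core < 4:
        raise ValueError("window too small for the wall-frame construction")
    # square core grid, slightly overfilled then thinned to the exact count
    m = int(np.ceil(np.sqrt(n_core)))
    gx = np.linspace(core_lo[0], core_hi[0], m)
    gy = np.linspace(core_lo[1], core_hi[1], m)
    core = np.array([(x, y) for y in gy for x in gx])
    if core.shape[0] > n_core:
        drop = rng.choice(core.shape[0], size=core.shape[0] - n_core, replace=False)
        core = np.delete(core, drop, axis=0)
    pts = np.vstack([frame, core])
    pts, _ = _relax(pts, window, spacing, n_iter, step)
    return PointPattern(pts, window, label=f"confined(n={n})")
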