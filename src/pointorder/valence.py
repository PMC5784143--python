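"""Entropic valence (first-neighbour probability) maps.

Every particle is translated to a common origin together with the
displacement vectors to its Voronoi neighbours; pooling these vectors
over all particles (each contributes as many points as its coordination
number) and histogramming them on a square grid yields a 2D probability
map of where neighbours sit relative to a typical particle — the
angular analogue of the pair correlation function.  Subsetting by
coordination number isolates e.g. the 5- and 7-fold disclination
defects, and rigidly rotating each particle's bond set to a common
orientation exposes the internal arc symmetry that an unoriented pool
would wash out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pattern import PointPattern
from .voronoi import VoronoiPartition

__all__ = ["BondCloud", "ValenceMap", "bond_cloud", "orient_clouds", "probability_map"]


@dataclass
class BondCloud:
    """Displacement vectors from one particle to its Voronoi neighbours."""

    particle_index: int
    vectors: np.ndarray  # (k, 2)
    facet_lengths: np.ndarray  # (k,)

    @property
    def coordination(self) -> int:
        return int(self.vectors.shape[0])


@dataclass
class ValenceMap:
    """Square 2D probability histogram of neighbour displacements.

    ``grid[ix, iy]`` covers ``[-R, R]^2`` with the first axis along x;
    values sum to 1 over deposited (in-range) points.
    """

    grid: np.ndarray
    R: float
    n_bins: int
    oriented: bool
    coordination_filter: int | None
    n_contributing: int
    n_deposited: int
    n_out_of_range: int

    @property
    def bin_centres(self) -> np.ndarray:
        w = 2.0 * self.R / self.n_bins
        return -self.R + w * (np.arange(self.n_bins) + 0.5)


def bond_cloud(
    pattern: PointPattern,
    partition: VoronoiPartition,
    coordination_filter: int | None = None,
    exclude_edge: bool = True,
) -> list[BondCloud]:
    """Per-particle neighbour displacement sets.

    With ``coordination_filter`` only particles whose coordination equals
    the filter value are kept; an empty result triggers a warning, not an
    error.  The total vector count equals the summed coordination of the
    included particles.
    """
    if partition.points is None:
        raise ValueError("partition lacks generator coordinates")
    if partition.n != pattern.n:
        raise ValueError("partition does not match pattern")
    pts = pattern.points
    clouds: list[BondCloud] = []
    for cell in partition.cells:
        if exclude_edge and cell.is_edge:
            continue
        if coordination_filter is not None and cell.coordination != coordination_filter:
            continue
        if not cell.facets:
            continue
        nbrs = np.fromiter(cell.facets.keys(), dtype=int)
        clouds.append(
            BondCloud(
                particle_index=cell.particle_index,
                vectors=pts[nbrs] - pts[cell.particle_index],
                facet_lengths=np.fromiter(cell.facets.values(), dtype=float),
            )
        )
    if coordination_filter is not None and not clouds:
        warnings.warn(
            f"no particles with coordination {coordination_filter}", RuntimeWarning
        )
    return clouds


def orient_clouds(
    clouds: list[BondCloud], rule: str = "longest_facet"
) -> list[BondCloud]:
    """Rigidly rotate each bond set so its reference bond points along +y.

    The reference bond is the neighbour subtending the longest Voronoi
    facet (``rule="longest_facet"``, the most strongly 'bonded'
    neighbour) or the first bond counter-clockwise from the +x axis
    (``rule="first_ccw"``).  Pairwise angles within a set are preserved
    exactly.
    """
    if rule not in {"longest_facet", "first_ccw"}:
        raise ValueError(f"unknown orientation rule {rule!r}")
    out: list[BondCloud] = []
    for cloud in clouds:
        if cloud.vectors.shape[0] == 0:
            raise ValueError("cannot orient an empty bond set")
        angles = np.arctan2(cloud.vectors[:, 1], cloud.vectors[:, 0])
        if rule == "longest_facet":
            ref = angles[int(np.argmax(cloud.facet_lengths))]
        else:
            ref = np.min(np.mod(angles, 2.0 * np.pi))
        rot = np.pi / 2.0 - ref
        c, s = np.cos(rot), np.sin(rot)
        mat = np.array([[c, -s], [s, c]])
        out.append(
            BondCloud(
                particle_index=cloud.particle_index,
                vectors=cloud.vectors @ mat.T,
                facet_lengths=cloud.facet_lengths.copy(),
            )
        )
    return out


def probability_map(
    clouds: list[BondCloud],
    n_bins: int = 64,
    R: float | None = None,
    *,
    oriented: bool = False,
    coordination_filter: int | None = None,
) -> ValenceMap:
    """Histogram pooled neighbour displacements into a probability map.

    ``R`` (map half-width) defaults to twice the mean bond length of the
    pooled cloud.  Out-of-range points are counted and reported; if all
    points fall outside the grid an error is raised.  Deposits are unit
    weights per neighbour — any smoothing is a rendering concern.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    if not clouds:
        raise ValueError("no bond clouds to map")
    pooled = np.vstack([c.vectors for c in clouds])
    if R is None:
        R = 2.0 * float(np.mean(np.linalg.norm(pooled, axis=1)))
    if R <= 0:
        raise ValueError("R must be positive")
    hist, _, _ = np.histogram2d(
        pooled[:, 0], pooled[:, 1], bins=n_bins, range=[[-R, R], [-R, R]]
    )
    deposited = int(hist.sum())
    if deposited == 0:
        raise ValueError("all displacement points fall outside the map range")
    return ValenceMap(
        grid=hist / deposited,
        R=float(R),
        n_bins=int(n_bins),
        oriented=oriented,
        coordination_filter=coordination_filter,
        n_contributing=len(clouds),
        n_deposited=deposited,
        n_out_of_range=int(pooled.shape[0] - deposited),
    )
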