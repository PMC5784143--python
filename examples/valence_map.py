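"""Entropic valence map of a jittered hexagonal pattern.

Pools every particle's Voronoi-neighbour displacement vectors at a
common origin and histograms them into a 2D probability map.  For a
near-hexagonal pattern the map shows six sharp spots at 60-degree arcs;
after orienting each particle's bond set so its strongest bond (longest
Voronoi facet) points along +y, the spots sharpen further.  The script
prints the angular positions of the strongest map bins.
"""

import numpy as np

import pointorder as po

spacing = po.hexagonal_spacing(1.0)
base = po.hexagonal_lattice(1.0, po.ObservationWindow(0, 0, 20, 20))
pattern = po.hexatic_ensemble(po.HexaticSpec(base, 0.05 * spacing, 1, seed=3))[0]

part = po.tessellate(pattern)
clouds = po.bond_cloud(pattern, part)
print(f"{len(clouds)} interior particles contribute "
      f"{sum(c.coordination for c in clouds)} neighbour vectors")

for label, cl in [("unoriented", clouds), ("oriented", po.orient_clouds(clouds))]:
    vmap = po.probability_map(cl, n_bins=48, R=1.5 * spacing,
                              oriented=label == "oriented")
    centres = vmap.bin_centres
    ix, iy = np.unravel_index(np.argsort(vmap.grid, axis=None)[-6:],
                              vmap.grid.shape)
    angles = np.degrees(np.arctan2(centres[iy], centres[ix]))
    print(f"{label}: 6 strongest bins at angles "
          f"{np.sort(np.round(angles))} degrees")
print("\n60-degree arc separations mark 6-fold entropic order; the oriented "
      "map pins one spot to +90 degrees by construction.")
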