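# Methods

This note records the models implemented in `pointorder`, the numerical
choices behind them, and what the synthetic test conditions do and do
not establish about real data.

## Point patterns and the observation window

All analyses operate on a `PointPattern`: N centroids inside an
axis-aligned rectangular observation window. The window is part of the
data, not a convenience — the intensity λ = N/A_box that normalizes
g(r) and fixes reference lattice spacings is defined with respect to
the *observed* field of view. When no window is supplied, the tight
bounding box of the points is used and recorded in the run manifest;
an explicit window always wins.

Coordinates follow the mathematical convention (origin lower-left, y
up). Image-convention tables (y down) are flipped once at read time via
a flag, so downstream constructs that reference the +y direction
(oriented valence maps) are consistent. Unit conversion likewise
happens exactly once at ingestion: if a pixel size is given (length per
pixel), coordinates and radii are multiplied into physical units and
every later computation is unit-agnostic. Whether an input table is in
pixels or physical units cannot be detected from the numbers alone; the
assumption applied is recorded in the manifest.

## Window-clipped Voronoi tessellation

The tessellation is computed on the pattern augmented with its mirror
images across the four window edges (reflection lines offset outward by
10⁻⁹ of the window diagonal so a point lying exactly on the boundary
never coincides with its own mirror). Every window location is strictly
closer to a real generator than to any mirror, so the real cells,
intersected with the window, tile it exactly: the cell areas sum to the
window area to machine precision. This identity is asserted at relative
10⁻⁹ in the tests and is the foundation of all density-derived metrics.

Cells whose clipped polygon touches the window boundary (vertex within
10⁻⁷ diagonal) are flagged as edge cells. Edge cells have truncated
neighbourhoods — counting them biases density and coordination — so all
summary statistics exclude them by default; the flag is exposed for the
cases where inclusion is wanted (the coordination histogram offers both
modes).

Facets shorter than `facet_epsilon` (default 10⁻⁶ of the window
diagonal) are dropped, symmetrically for both cells of the pair. This
resolves degenerate point contacts deterministically: in an exact
square lattice four cells meet at each vertex and the diagonal
"neighbours" subtend zero-length facets, so interior coordination is 4;
any perturbation larger than the threshold splits the vertices and
diagonal facets become real, moving the mean interior coordination
toward the planar-tessellation limit of 6 (individual cells then range
over roughly 4–8). Coincident generators (closer than 10⁻¹² diagonal)
are an error, not a silent merge: the tessellation is undefined there.

## Local spacing and the lattice disorder parameter

A regular hexagon with apothem r has area 2√3·r², so a Voronoi cell of
area A_vor corresponds to a local hexagonal radius
r_hex = √A_vor·(2√3)^(-1/2), and a triangular lattice of intensity λ
has nearest-neighbour spacing 2r_hex = (2/(λ√3))^(1/2). The mean local
spacing ⟨2r_hex^vor⟩ is the average of 2·r_hex over interior cells (at
least three are required).

The lattice disorder parameter Δr is the spread of r_hex over interior
cells. Two estimators are reported:

* `delta_r_variance` — the sample standard deviation of the r_hex
  values (the canonical value);
* `delta_r_propagated` — first-order error propagation
  |∂r_hex/∂A|·σ_A with the derivative evaluated at the mean interior
  area (the evaluation point is a choice of this package; any point
  within the observed area range changes the result only at second
  order).

Both vanish for a perfect lattice and agree to within a few percent in
the small-disorder regime where the linearization is valid; the
agreement degrades as disorder grows, which is why both are kept.
Sample (ddof = 1) standard deviations are used throughout.

On Gaussian-jittered lattices the estimated Δr is a fixed fraction
(≈ 0.205, calibrated once against the generator at unit intensity) of
the per-axis displacement scale: jitter perturbs each cell through all
of its neighbours, and the area fluctuation per cell is smaller than
the displacement itself. The estimator is therefore a monotone index of
translational disorder rather than an unbiased displacement estimate,
which is how it is used in the reports.

## Pair correlation function

g(r) = n_n(r)/(2πrΔr·ρ) with ρ = N/A_box; n_n(r) is the mean ordered
pair count per particle in the shell [r−Δr/2, r+Δr/2). Bins are centred
at integer multiples of Δr, so lattice shell distances fall exactly on
bin centres when Δr divides them; r in the denominator is the bin
centre. Self-pairs are excluded; each unordered pair contributes once
per centre. Defaults: Δr = ⟨2r_hex^vor⟩/20 and
r_max = min(5·⟨2r_hex^vor⟩, half the shorter window side); a larger
r_max is allowed with a warning.

No edge correction is applied by default, so g(r) sags below 1 at
distances comparable to the window size (missing neighbours outside the
field of view). An optional isotropic correction divides each bin by
the mean fraction of the circle of that radius lying inside the window,
evaluated on a fixed 1440-point angular grid (deterministic, accurate
to ~10⁻³); it is off by default so that cross-sample comparisons share
the same bias.

The triangular-lattice reference g(r) deposits each neighbour shell
(distance √(i²+ij+j²) in spacing units, multiplicity from exact
enumeration of the integer quadratic form) as a single-bin impulse with
the same shell-area normalization. Broadened references are obtained by
running g(r) on jittered-lattice ensembles instead.

The bootstrap estimator averages g(r) over an ensemble of copies of the
pattern, each independently Gaussian-shaken (per-axis standard
deviation σ) about the observed positions — the displacement scale
plays the role of the centroid-detection uncertainty, typically half a
pixel. With σ = 0 it reduces exactly to the plain estimator. It
suppresses single-bin spikes that are artifacts of the finite distance
set in small-N patterns; it cannot add information beyond the observed
configuration.

Difference spectra Δg(r) = g_a − g_b require both operands to be
distance- and height-normalized; b is linearly interpolated onto a's
bins over the overlapping range (no extrapolation). Δ_rms is the RMS of
Δg over the compared range — the precise functional form is a choice of
this package and is recorded in the manifest. Ordered-versus-unordered
pair counting cancels under height normalization; raw-mode output
documents the ordered convention.

## Bond orientational order

Bonds (Voronoi-facet neighbours only — no cutoff radius and no Delaunay
fallback, avoiding neighbour-definition bias) are embedded in the
equatorial plane of the spherical-harmonic frame: polar angle π/2,
azimuth = bond angle from +x. This is the standard planar reduction and
makes q_ℓ a function of bond azimuths alone; with orthonormalized
harmonics (Condon–Shortley phase) any consistent convention gives the
same q_ℓ, which the rotation-invariance test verifies numerically at
10⁻¹⁰.

Weights are facet lengths normalized per particle (Minkowski variant,
default) or uniform 1/n. Weights sum to one, so the addition theorem
gives 0 ≤ q_ℓ ≤ 1 with equality at 1 exactly for a single bond
direction. Normalization constants q_ℓ^sym (perfect ℓ-fold star at arc
spacing 2π/ℓ, equal weights) are computed numerically at first use and
cached — never hard-coded; q_4^sym has the closed form √11/4 ≈ 0.8292
and q_6^sym ≈ 0.7408. Edge particles are excluded from ⟨q_ℓ⟩ by
default. Note that odd-ℓ values vanish identically on perfect
even-symmetric stars (equatorial harmonics with odd ℓ+m are zero), so
e.g. q_5 = q_7 = 0 on a perfect triangular lattice.

## Entropic valence maps

Per-particle neighbour displacement sets (one vector per retained
facet) are pooled at a common origin and histogrammed on an n×n grid
covering [−R, R]²; counts are unit weights per neighbour, normalized to
probability 1 over deposited points, with out-of-range points counted
and reported. Each particle contributes exactly its coordination number
of points. R defaults to twice the mean bond length; smoothing is left
to rendering.

The orientation rule for oriented maps is not canonical; the default
rotates each particle's set so the neighbour subtending the *longest
facet* (the most strongly "bonded" neighbour) points along +y, with
"first bond counter-clockwise from +x" as a deterministic alternative.
The rule travels in the manifest because oriented maps are only
comparable under the same rule.

## Synthetic patterns (the test conditions)

* **Lattices** are generated on an extended grid anchored at the window
  centre, then cropped, so patterns are stable under window resizing;
  realized N is within one row/column of λ·A_box.
* **Hexatic ensembles** displace every site independently with an
  isotropic per-axis Gaussian of scale Δr, always about the base
  positions (never chained). A displacement scale with "variance" in
  length units is ill-formed, so the scale is interpreted as the
  per-axis standard deviation. Displaced points are clamped to the
  window; at the scales used (Δr ≪ window) the clamping affects a
  negligible boundary fraction.
* **CSR** draws N ~ Poisson(λ·A_box) with uniform positions.
* **The confined packing** is a constructed fixture: two hexagonally
  stacked rows hugging each hard wall around a square-packed core,
  smoothed by a short soft-repulsion relaxation (linear force below a
  cutoff of 1.6 mean spacings, fixed step, hard-wall clamping). For
  n < 60 the points instead relax from a jittered grid under pure
  repulsion, which drives the minimal cases toward the corners. It
  reproduces the qualitative wall-hexagonal/core-square morphology of
  square confinement and nothing more — no thermodynamic claim.

All stochastic generators take an explicit integer seed; there is no
global random state, and identical seeds give byte-identical patterns.

These conditions emulate the structure of micrograph-derived centroid
tables (hundreds of points, bounded window, near-hexagonal order with
Gaussian positional noise) but not their full phenomenology: no
polydispersity, no detection errors (missed/split particles), no
spatially correlated drift, no true thermal ensembles. Passing tests
demonstrate the estimators' analytic identities and monotone response
to controlled disorder, not detector-level robustness.

## Problem sizes and determinism

Test and reference computations use windows of roughly 10–30 lattice
spacings (a few hundred to a few thousand points), ensembles of 3–10
realizations for recovery sweeps, 200 realizations for bootstrap
behaviour, and N ≈ 5000 (bond order) to N ≈ 160 000 (g(r) flatness) for
the randomness limits — sizes chosen so every property is measured well
inside its asymptotic regime while the whole suite remains quick on one
CPU. Reports embed every seed and defaulted parameter in their
manifest; re-running with the same manifest reproduces all numbers
exactly.

## Known limitations

* Tessellation metrics assume a rectangular window; arbitrary polygonal
  masks are not supported.
* Laguerre (radius-weighted) tessellations are not implemented, so
  polydisperse packings are treated by centroids only.
* The pair correlation estimator is 1D (radially averaged); vector-
  resolved maps are covered only through the valence-map machinery.
* Δ_rms depends on the compared range and binning; it is comparable
  across samples only under a shared manifest.
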