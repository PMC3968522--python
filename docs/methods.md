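# Methods

## Model

Two steady Darcy compartments coexist at every point of the lobule
cross-section: the sinusoidal network (pressure `p_S`, mobility
`a = k_S/mu_S`) and the interstitium/space of Disse (pressure `p_I`,
mobility `b = k_I/mu_I`). They exchange volume through the fenestrated
endothelium at rate `q_w = C_f (p_S - p_I)` per unit tissue volume, and the
interstitium loses volume to lymphatic ducts at
`q_l = C_l max(p_I - p_0, 0)`, where `p_0` is the pressure of the flowing
lymph and the `max` encodes lymphangion valves. Oncotic pressure
differences, tissue compliance, non-Newtonian rheology and axial (3D)
variation are all outside the model's scope, consistent with its steady,
rigid, two-dimensional formulation.

Boundary conditions: `p_S` is Dirichlet at the portal-tract and
central-vein walls and no-flux everywhere else (vascular septa are
impermeable to blood); `p_I` is no-flux at vessel walls and symmetry lines,
continuous (value and flux) across septa, and obeys a membrane law
`u_I . n = M (p_I - p_ext)` on the liver surface. The bare area's
conductance is taken as infinite and is imposed as the Dirichlet limit
`p_I = p_DS`; a penalized Robin condition with a huge `M` would be
numerically fragile for no benefit.

A model variant extends the interstitial equation into the vessel
cross-sections themselves (`-b lap p_I + q_l = 0` there, no filtration),
with pressure/flux continuity at the vessel wall. At baseline it raises
predicted lymph uptake by ~1% and leaves blood flux essentially unchanged,
which is why the standard variant treats vessel walls as no-flux for `p_I`.

## Parameters

All parameters live in one frozen dataclass (SI internally; configs accept
mmHg-based units). Defaults describe a normal adult human liver:
`L_lob = 500 um`, `D_PT = 50 um`, `D_CV = 75 um`, `V_liv = 1474 cm^3`,
`A_liv = 1190 cm^2`, bare-area fraction `chi = 0.2`,
`k_S = 1.56e-14 m^2`, `k_I = 0.002 k_S`, `mu_S = 2.4 mPa s`,
`mu_I = 1.8 mPa s`, `C_f = 5.3e-5 /(mmHg s)`, `C_l = 5.9e-7 /(mmHg s)`,
`p_S,PT = 4.4 mmHg`, `p_S,CV = 1.5 mmHg`,
`M_GP = 2.15e-8 m/(s mmHg)`, `M_BA = inf`, and
`p_0 = p_DS = p_PC = 0`. Overriding `k_S` without an explicit `k_I`
preserves the `k_I = 0.002 k_S` proportionality, since the interstitial
permeability estimate is tied to the sinusoidal one.

The governing screening length of sinusoidal/interstitial disequilibrium is

    lambda = sqrt[ a b / (C_f (a + b)) ]  ~  209 um  at baseline,

which is why surface effects die out within roughly one lobule of the
boundary and a single interior lobule suffices for the bulk quantities.

## Geometry

*Single lobule.* Regular hexagon with side = circumradius = `L_lob`
(pointy-top orientation), so neighbouring portal tracts are exactly
`L_lob` apart; one full CV disk at the centroid, six 120-degree PT wedges
at the vertices.

*Square-lattice variant.* Side `s = sqrt(3 sqrt(3)/2) L_lob` preserves the
cross-sectional area exactly; corner PT radii are scaled by `sqrt(2)` so
four quarter-disks equal the hexagon's six third-disks, preserving the
vessel area fractions to machine precision.

*Near-surface slab.* One mirror-symmetric half lattice period
(`0 <= x <= sqrt(3) L_lob / 2`) standing on a flat surface. The flat
surface passes `L_lob/4` below the nearest PT row and `3 L_lob/4` below
the nearest CV row; the outermost (pentagonal) lobule is the hexagon with
everything below its lower PT row replaced by a rectangle reaching the
surface, which reproduces the equal-area property of the cut lobules
exactly. The stack is terminated above by a horizontal symmetry line
through a CV row (a far-field approximation). Defaults of 4 rows
(Glisson–peritoneal) and 6 rows (bare area) leave the innermost cell's
interstitial pressure within 0.5% of the single-lobule solution;
`choose_slab_rows` re-derives the count adaptively, and the interstitial
permeability sweep raises the bare-area stack to 10 rows for
`k_I > 2x` default, where the boundary layer is thicker.

*Whole-liver scaling.* Any 2D flux density is multiplied by
`V_liv / (3 sqrt(3) L_lob^2 / 2)` (the total lobule axial length in the
organ). Surface integrals are additionally scaled by
`(1-chi) A_liv / L_edge` (membrane) or `chi A_liv / L_edge` (bare area).
Since the slab solution does not depend on `chi`, the bare-area comparison
reuses the same two slab solves for every `chi`.

## Discretization

The domains are convex polygons minus vessel disks whose centres lie on
polygon vertices, edges or the interior. The mesher samples clipped polygon
edges and in-domain circular arcs at the target spacing, fills the interior
with a triangular lattice keeping a clearance of 0.72 local boundary
spacings (which makes every boundary chord a Gabriel edge, hence present in
the Delaunay triangulation), triangulates with `scipy.spatial.Delaunay`,
discards triangles whose centroid leaves the domain, and verifies through
node provenance that the recovered boundary conforms to the geometry —
any non-conforming edge raises rather than silently degrading. Septum
segments shared by two cells are sampled in a canonical orientation so both
cells produce bitwise-identical node coordinates; the solver merges those
into a single continuous interstitial unknown while keeping each cell's
sinusoidal unknowns separate, which realizes "blood stays inside its
lobule, interstitial fluid crosses freely" without Lagrange multipliers.

Both fields use continuous P1 elements. Diffusion is assembled exactly; the
reaction terms (`C_f`, `C_l`) and the Robin surface mass use lumped
(diagonal) mass. Lumping is a deliberate choice: it keeps the discrete
operator an M-matrix (discrete maximum principle for `p_S`), makes the
valve clamp exactly nodal, and — because lumped and consistent mass have
equal row sums — makes the discrete mean-pressure identity

    mean(p_I) = (C_f mean(p_S) + C_l p_0) / (C_f + C_l)

and all global mass balances hold to linear-solver precision (observed
residuals ~1e-13 relative).

The `max(., 0)` nonlinearity is resolved by a primal active-set iteration:
nodes with `p_I > p_0` are active, ties count as inactive, and the loop
stops when the nonlinear residual is below tolerance or the mask is stable
(monotone; at default `p_0 = 0` the first, fully active solve is already
exact). Linear systems are solved by sparse direct factorization — they
are small (1e4–1e5 unknowns) and the iteration count stays in single
digits.

Boundary fluxes are extracted from the residual of the Neumann-assembled
system (consistent flux extraction), not from gradient sampling, so
discrete conservation statements hold exactly: portal influx minus
central-vein outflux equals the filtration integral, and filtration equals
lymph uptake plus surface outflow, each to ~1e-13 relative.

## Verification oracles

The solver is judged against closed forms derived independently of it:

- *Annulus*: `p_S` Dirichlet at both radii, `p_I` no-flux. After removing
  the constant particular solution, the coupled system diagonalizes into
  two screened modes (modified Bessel `I_0/K_0`); with `C_l = 0` one mode
  degenerates to the harmonic `(1,1)(c_0 + c_1 ln r)` pair. Coefficients
  come from a 4x4 boundary system. The closed form is itself validated
  against a dense second-order radial finite-difference solve (agreement
  at the FD oracle's own 1e-5 discretization level) before being used to
  judge the 2D solver, which matches it to < 0.5% in the max norm at
  moderate refinement.
- *Half-space boundary layer*: the same diagonalization in 1D depth, with
  no blood flux and a Robin (or Dirichlet) interstitial condition at the
  wall. A bounded half-space solution with nonzero surface outflow needs
  the `C_l` sink (with `C_l = 0` the drained volume must arrive from
  infinity along a linear-in-depth mode), so the oracle is posed on a
  finite depth — default 12 decay lengths — with the far-field blood
  pressure pinned and interstitial no-flux at the truncation. It is also
  validated against a 1D finite-difference solve.
- *Mean-pressure identity* and a battery of exact limits (`C_f = 0` pins
  `p_I = p_0`; uniform boundary data give constant fields and zero
  fluxes; the solution map is affine in the boundary pressures at fixed
  active set).

## Problem sizes and numerical defaults

Quantitative runs use a 10 um target edge (1/50 of the lobule side;
~7.5e3 nodes per lobule cell, ~2e4 interstitial nodes for the six-row
slab), where the whole-liver fluxes are converged to well under 1%
(successive refinement 20 -> 10 -> 5 um moves the blood flux by 0.7% then
0.08%). Sign/structure checks in the test suite use 15–18 um. The
mesh-convergence sequence is available from the CLI
(`lobuleflow report --convergence`).

Sweeps use 3–9 points centred on baseline; sensitivity slopes are ordinary
least squares over the points with a fully active lymph set, where the
response is provably affine (fit residuals at rounding level serve as a
linearity check). The external-pressure sweep sets the peritoneal and
diaphragmatic pressures together, as is conventional.

The square-lattice comparison computes blood flux and lymphatic uptake
directly on the square lobule. Its surface flux is estimated by scaling
the hexagonal-lattice surface flux with the square/hexagon ratio of the
interior mean interstitial excess pressure — the far-field drive of the
linear near-surface problem — rather than by building a square-lattice
surface slab, whose cut construction has no uniquely natural analogue.

## What the tests do and do not show

All quantitative checks run on the idealized geometry with the default
parameter set: identical hexagonal prisms, perfectly circular vessels, a
flat surface with face-on lobules, and literature point estimates for
permeabilities and exchange coefficients. Passing them shows the
implementation solves this model correctly and reproduces its published
organ-scale predictions; it does not validate the model against irregular
real lobule geometry, end-on surface orientation, parameter heterogeneity,
or disease-state physiology (fibrosis, vasodilation), none of which are
modelled. Predicted pressures are inputs, not outputs: portal hypertension
scenarios move `p_S,PT` by hand rather than emerging from a vascular tree
model.

## Known limitations

- The slab truncation (horizontal symmetry line through a CV row) is an
  approximation of the infinite interior; with default row counts its
  effect on surface fluxes is below the mesh error.
- The bare-area Dirichlet limit is one reading of an "infinite
  conductance" surface; the Robin law with finite `M_BA` is available for
  sensitivity checks.
- P1 elements with lumped reactions are first-order near the vessel-wall
  pressure singularities; boundary-flux superconvergence of the consistent
  extraction keeps integral fluxes accurate regardless.
- The active-set loop assumes the discrete operator stays an M-matrix;
  strongly graded anisotropic meshes (not produced by this mesher) could
  break the monotonicity argument.
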