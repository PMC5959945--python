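# Methods

This note describes the physical model, its discretization, the synthetic
fixtures, and the numerical choices made in `vapor`. It is the reference
for what the package computes; empirical numbers quoted here are the ones
produced by the test suite and `scripts/acceptance.py`.

## Model overview

The head is a 3D voxel continuum (the *porous domain*) threaded by 1D
arterial and venous vessel trees. Four temperature fields interact:

1. arterial blood in discrete vessel segments (1D nodes),
2. solid tissue in each voxel,
3. capillary (porous) blood in each voxel,
4. venous blood in discrete vessel segments (1D nodes).

Within brain voxels the tissue–capillary heat exchange is taken as
infinitely fast, so domains 2 and 3 share one unknown per voxel
(`T2 = T3`); their energy balances are summed and the inter-domain term
cancels algebraically. Outside the brain the blood volume fraction
`eps3` is zero and the voxel carries the classical Pennes perfusion sink
instead.

### Tissue voxel balance

Steady state, per voxel of edge `l` (volume `V = l^3`):

- **Conduction** between face-adjacent voxels with harmonic-mean face
  conductivity; in brain voxels the effective conductivity is the
  volume-fraction mix `K_eff = eps2*K_tissue + eps3*K_blood`.
- **Metabolic generation** `Q_gen * V`, a fraction-weighted mix of the
  per-class rates.
- **Porous advection** of capillary blood enthalpy between adjacent
  brain voxels, first-order upwinded on the Darcy face fluxes.
- **Counter-current exchange**: the net face flux `q` is split into a
  forward stream `C_R*q` and a reverse stream `-(C_R-1)*q`, each
  upwinded independently. `C_R = 1` reduces exactly to plain upwind
  (bit-identical matrix); `C_R > 1` adds a symmetric positive exchange
  operator that raises effective diffusivity along flow paths, the
  discrete analogue of counter-current heat exchange between apposed
  arterioles and venules.
- **Vessel coupling** (brain voxels intersected by vessel segments):
  convective exchange with the 1D vessel node, coefficient
  `beta = Nu * K_blood * pi * L / N` per segment of length `L`
  intersecting `N` voxels — the segment diameter cancels against the
  laminar-tube heat-transfer coefficient. The coefficient is split
  `eps2 : eps3` between the (merged) tissue and capillary channels.
- **Terminal mass transfer**: at arterial branch terminations blood
  leaves the 1D tree and enters the porous domain (and symmetrically is
  drained at venous terminations), with enthalpy `c_b * Mdot * T`
  carried at the upstream temperature. Each termination deposits its
  mass equally over the brain voxels its final segment intersects.
- **Perfusion sink** (non-brain voxels only):
  `c_b * omega_vol * (T - T_a)`.

### Vessel node balance

Each 1D node balances axial conduction (`K_b * pi * D^2 / (4 L)`),
upwinded advection `c_b * F` along each segment, and the `beta` coupling
to every intersected voxel, attached to the downstream node of the
segment. Arterial inlets are Dirichlet at the body temperature `T_a`;
venous outlets use an advective-outflow closure (no axial diffusion
across the outlet, enthalpy leaves with the flow). The `beta` and
conduction terms of an outlet segment re-attach to its upstream node so
the global energy budget closes.

### Boundary conditions

The outermost tissue shell (any voxel with an air-adjacent face, or on
the grid edge) is Dirichlet at the scalp temperature `T_scalp`
(33.5 degC warm cap, 10 degC cooled cap by default).

## Blood flow

- **Vessel flows** are determined by mass balance alone: boundary
  inflows (default split 40/40/20 over the two carotids and the
  basilar, 50/50 over the venous outlets) propagate down the tree; each
  branch termination receives mass in proportion to its final-segment
  length, normalized within the subtree nearest each boundary node.
- **Diameters** follow the empirical flow-diameter law
  `D = 0.0332 * F^0.3703` (F in kg/s, D in m). For 40% of a 14.1 g/s
  total inflow this gives a 4.9 mm internal carotid with a mean
  velocity of ~0.29 m/s.
- **Porous flow** between brain voxels is Darcy flow with a
  Carman–Kozeny conductance
  `G = rho_b * eps3 * l * pi * D_c^2 / (32 * mu_b * tau)`
  (~3.7e-10 m s for grey-matter defaults). Pressure solves a graph
  Laplacian per connected brain component with terminal sources/sinks
  on the right-hand side; one reference voxel per component pins the
  gauge. Because the same `G` scale multiplies every face and the
  sources fix the net fluxes, the velocity field is invariant to a
  uniform rescaling of `G` — which is why capillary diameter `D_c` and
  tortuosity `tau` do not affect temperatures (verified to < 0.001 degC
  in the acceptance suite).
- **Total inflow** for phantom trials defaults to the perfusion
  integral over the brain mask, which keeps vessel flow and porous
  perfusion exactly consistent (and reproduces ~14.1 g/s at real adult
  brain volume).

## Vessel generation (RRT)

Synthetic trees grow by rapidly-exploring random tree expansion:
each iteration samples a voxel with probability proportional to its
perfusion, samples a uniform point inside it, finds the nearest point on
any existing segment, and connects — capping the step at 3 mm by
steering toward the sample. Samples falling outside the brain or
producing degenerate connections are resampled, so exactly
`n_iterations` generated nodes are added (attachment to a segment
interior also inserts a junction node). Segment counts therefore track
the perfusion field: two equal-area regions weighted 4:1 receive
segments in a ratio statistically indistinguishable from 4:1.

## Pennes baseline

`pbe_steady_solve` solves the classical steady Pennes equation on the
same voxel grid — conduction, metabolism, and the perfusion sink
`c_b * omega_vol * (T - T_a)` in *every* tissue voxel including brain,
with the same scalp Dirichlet shell — and is the comparison model for
the temperature-shielding question.

## Synthetic phantom

`PhantomSpec`/`make_phantom_head` build a five-layer concentric
ellipsoidal head (scalp, skull, CSF, grey, white) on a configurable
grid; three arterial anchors (two carotid-like, one basilar-like) and
two venous anchors (transverse-sinus-like) seed the trees. The phantom
reproduces the *structure* of the problem — layered conduction path,
perfused brain interior, vascular convection from the neck — not the
anatomy; absolute temperatures are therefore phantom-specific, and only
trends (vascular vs Pennes, C_R, neonatal scaling, grid refinement) are
meaningful. A neonatal variant shrinks the voxel edge by 11/15,
rescales perfusion to a 30 ml/100g/min brain mean, and halves
metabolism.

## Numerical choices

- Conduction: second-order central differences, harmonic-mean face
  conductivities. Advection: first-order upwind; conservation relies on
  the exact discrete mass balance of the flow solve (closed to ~1e-16
  relative).
- Linear systems: ILU-preconditioned GMRES (drop tolerance 1e-5, fill
  factor 20, rtol 1e-14) with a sparse direct fallback; every solution
  is accepted only if the relative residual is <= 1e-10. On the default
  phantom (~32k unknowns) this is roughly 10x faster than a direct
  solve at machine-precision residuals.
- Energy audit: `energy_budget` checks metabolic + inlet enthalpy
  against outlet enthalpy + surface conduction + non-brain perfusion
  exchange; it closes to ~1e-15 relative on the phantom.
- A `printed_sign_mode` switch flips the terminal-enthalpy orientation
  to an alternative (non-conserving) sign convention for comparison;
  the default is the energy-conserving orientation.

## Known limitations

- The cold-cap temperature field near the scalp and near terminal
  source voxels is resolution-sensitive: refining the voxel edge from
  3 mm to 2.25 mm on the phantom changes brain temperatures by ~0.2%
  on average (warm case alone ~0.06%). The dominant contributions are
  boundary voxelization (the brain/surface masks shift by a fraction of
  a voxel between grids under the steep cooled-scalp gradient) and the
  averaging of terminal mass sources over single voxels. The effect
  shrinks as the domain grows; at desk-scale phantom sizes it does not
  reach the sub-0.1% regime.
- First-order upwind advection introduces numerical diffusion along
  flow paths; it is conservative but smears sharp thermal fronts.
- Steady state only; no transient solver.
- One-dimensional vessel segments exchange heat with voxels through a
  constant-Nusselt laminar coefficient; vessel wall and pulsatility
  effects are not modelled.
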