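# vapor — vascular porous brain bioheat simulation

`vapor` predicts steady-state brain temperature by coupling discrete 1D
arterial and venous vessel trees to a 3D porous-tissue voxel continuum.
Classical perfusion-only models (the Pennes bioheat equation) predict a
*temperature shielding* effect: surface cooling of the scalp penetrates
only the outer rim of the brain, because perfusion pins deep tissue to
the arterial blood temperature. Resolving the vasculature changes that
picture — blood that is itself cooled on its way through scalp and
cortex carries the cold inward, so a cooled cap reaches the brain core
noticeably more than Pennes predicts. This package implements both
models side by side, plus the machinery around them:

- **Geometry**: tissue-probability maps (grey, white, CSF, bone, scalp)
  on a voxel grid, NIfTI I/O, mixed-voxel thermal properties, neonatal
  scaling, and a five-layer ellipsoidal head phantom.
- **Vasculature**: SWC vessel-tree I/O, perfusion-weighted
  rapidly-exploring random tree (RRT) generation, exact voxel
  rasterization, and the empirical flow–diameter law
  `D = 0.0332 F^0.3703`.
- **Flow**: mass-conservative vessel flows with terminal transfer into
  the porous domain, and Darcy capillary flow with Carman–Kozeny
  conductance.
- **Thermal**: the coupled four-domain steady energy balance with
  upwinded porous advection, a counter-current flow-reversal model
  (`C_R`), vessel–voxel heat exchange, and the Pennes baseline.
- **Experiments**: scalp-cooling trials with replicate statistics,
  parameter sweeps, mesh-refinement checks, and a Pennes comparison.

See `docs/methods.md` for the model equations, discretization, and
known limitations.

## Worked example

Build a phantom head, grow vessel trees, solve blood flow, and compare
a warm (33.5 °C) and a cooled (10 °C) scalp:

```python
import numpy as np
import vapor as vp

# 1. Synthetic five-layer head phantom on a 30x36x30 grid of 3 mm voxels
spec = vp.PhantomSpec(grid_shape=(30, 36, 30))
params = vp.PhysicalParams()
domain = vp.build_domain(vp.make_phantom_head(spec), params)
print(f"brain voxels: {domain.brain_mask.sum()}, "
      f"core voxels: {domain.core_mask.sum()}")

# 2. Grow arterial and venous trees by perfusion-weighted RRT
art, ven = vp.make_seed_trees(spec)
art = vp.rrt_expand(art, domain, 400, rng_seed=1)
ven = vp.rrt_expand(ven, domain, 400, rng_seed=2)
print(f"arterial segments: {len(art.segments)}, "
      f"venous segments: {len(ven.segments)}")

# 3. Solve vessel and porous blood flow (inflow = brain perfusion integral)
total_flow = float((domain.perfusion_vol[domain.brain_mask]
                    * domain.voxel_volume).sum())
art, ven, flow = vp.solve_flow(art, ven, domain, params,
                               total_flow=total_flow)
print(f"total inflow: {total_flow * 1e3:.2f} g/s")

# 4. Steady temperatures under a warm (33.5 C) and a cooled (10 C) cap
warm = vp.vapor_steady_solve(domain, art, ven, flow, params, t_scalp=33.5)
cold = vp.vapor_steady_solve(domain, art, ven, flow, params, t_scalp=10.0)
brain, core = domain.brain_mask, domain.core_mask
print(f"warm cap: brain {warm.mean_over(brain):.2f} C, "
      f"core {warm.mean_over(core):.2f} C")
print(f"cold cap: brain {cold.mean_over(brain):.2f} C, "
      f"core {cold.mean_over(core):.2f} C")
print(f"core drop: {warm.mean_over(core) - cold.mean_over(core):.2f} C")

# 5. Pennes baseline for the same domain
pbe_warm = vp.pbe_steady_solve(domain, params, t_scalp=33.5)
pbe_cold = vp.pbe_steady_solve(domain, params, t_scalp=10.0)
print(f"Pennes core drop: "
      f"{pbe_warm.mean_over(core) - pbe_cold.mean_over(core):.2f} C")
```

Output:

```
brain voxels: 4960, core voxels: 1208
arterial segments: 505, venous segments: 509
total inflow: 1.58 g/s
warm cap: brain 36.82 C, core 37.09 C
cold cap: brain 33.69 C, core 36.52 C
core drop: 0.57 C
Pennes core drop: 0.22 C
```

The vascular model carries more than twice the core cooling of the
Pennes baseline on the same domain — cooled blood, not conduction, is
the transport path into the deep brain. Absolute values are
phantom-specific; see `docs/methods.md` for what the phantom does and
does not emulate.

Higher-level drivers live in `vapor.experiments`
(`run_cooling_trial`, `sweep`, `run_mesh_refinement`,
`compare_with_pbe`), and a CLI is installed as `vapor`
(`vapor make-phantom`, `vapor run`, `vapor sweep`).

## Tests

```sh
python -m pytest -q tests/
```

The suite covers closed-form oracles (flow–diameter law, analytic
perfused-slab profile, analytic ellipsoid volumes), conservation
properties (global mass balance, steady energy-budget closure),
discretization identities (`C_R = 1` equals plain upwind to machine
precision), statistical checks on the RRT generator, and end-to-end
cooling trials. `tests/test_acceptance.py` holds the headline
quantitative checks at their stated tolerances; it exercises the full
pipeline and takes a few minutes.

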