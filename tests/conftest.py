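import numpy as np
import pytest

import vapor as vp


@pytest.fixture(scope="session")
def params():
    return vp.PhysicalParams()


@pytest.fixture(scope="session")
def small_spec():
    # smallest phantom whose CSF shell is still >= one voxel thick
    return vp.PhantomSpec(grid_shape=(30, 36, 30))


@pytest.fixture(scope="session")
def small_map(small_spec):
    return vp.make_phantom_head(small_spec)


@pytest.fixture(scope="session")
def small_domain(small_spec, small_map, params):
    return vp.build_domain(small_map, params)


@pytest.fixture(scope="session")
def seed_trees(small_spec):
    return vp.make_seed_trees(small_spec)


@pytest.fixture(scope="session")
def expanded_trees(seed_trees, small_domain):
    art, ven = seed_trees
    art = vp.rrt_expand(art, small_domain, 150, rng_seed=11)
    ven = vp.rrt_expand(ven, small_domain, 150, rng_seed=12)
    return art, ven


@pytest.fixture(scope="session")
def total_flow(small_domain):
    d = small_domain
    return float((d.perfusion_vol[d.brain_mask] * d.voxel_volume).sum())


@pytest.fixture(scope="session")
def flow_solution(expanded_trees, small_domain, params, total_flow):
    art, ven = expanded_trees
    return vp.solve_flow(art, ven, small_domain, params, total_flow=total_flow)


@pytest.fixture(scope="session")
def warm_cold_fields(flow_solution, small_domain, params):
    art, ven, flow = flow_solution
    warm = vp.vapor_steady_solve(small_domain, art, ven, flow, params, 33.5)
    cold = vp.vapor_steady_solve(small_domain, art, ven, flow, params, 10.0)
    return warm, cold


def make_slab_domain(n, voxel_edge, k, rho_c, q_gen, perf_vol, brain=False,
                     eps3=0.0, kb=0.492):
    """1D slab as a (n,1,1) porous domain with Dirichlet only at the ends."""
    shape = (n, 1, 1)
    ones = np.ones(shape)
    mask = np.ones(shape, dtype=bool)
    surface = np.zeros(shape, dtype=bool)
    surface[0] = surface[-1] = True
    return vp.PorousDomain(
        voxel_edge=voxel_edge,
        brain_mask=mask if brain else np.zeros(shape, dtype=bool),
        core_mask=np.zeros(shape, dtype=bool),
        tissue_mask=mask,
        surface_mask=surface,
        rho_c=ones * rho_c,
        conductivity=ones * k,
        q_gen=ones * q_gen,
        perfusion_vol=ones * perf_vol,
        perfusion_clinical=ones,
        eps3=ones * eps3 if brain else ones * 0.0,
        eps2=ones * (1 - eps3) if brain else ones,
    )
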