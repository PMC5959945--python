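import logging

import numpy as np
import pytest

import vapor as vp
from vapor.flow import (
    ConservationError,
    TopologyError,
    assign_terminal_mass_transfer,
    porous_divergence,
    solve_porous_pressure,
    terminal_sources_to_voxels,
)


def chain_tree(lengths, side="arterial"):
    """Straight chain along x with given segment lengths (m)."""
    xs = np.concatenate([[0.0], np.cumsum(lengths)])
    nodes = [[x, 0.0, 0.0] for x in xs]
    segs = [(i, i + 1) for i in range(len(lengths))]
    return vp.VesselTree(nodes, segs, side=side, boundary_nodes=[0])


def y_tree(side="arterial"):
    """Inlet -> junction -> two equal-length leaves."""
    nodes = [[0, 0, 0], [1e-2, 0, 0], [2e-2, 1e-2, 0], [2e-2, -1e-2, 0]]
    return vp.VesselTree(nodes, [(0, 1), (1, 2), (1, 3)], side=side,
                         boundary_nodes=[0])


class TestTerminalMassTransfer:
    def test_length_proportional_split(self):
        """1 mm and 3 mm terminations of 14.1 g/s get 3.525 and 10.575."""
        nodes = [[0, 0, 0], [5e-3, 0, 0], [5e-3 + 1e-3, 1e-3, 0],
                 [5e-3 + 3e-3, -3e-3, 0]]
        # make leaf segment lengths exactly 1 mm and 3 mm
        nodes[2] = [6e-3, 0, 0]
        nodes[3] = [8e-3, 0, 1e-9]
        tree = vp.VesselTree(nodes, [(0, 1), (1, 2), (1, 3)],
                             boundary_nodes=[0])
        mass = assign_terminal_mass_transfer(tree, 0.0141)
        vals = sorted(1e3 * m for m in mass.values())
        assert vals[0] == pytest.approx(3.525, rel=1e-9)
        assert vals[1] == pytest.approx(10.575, rel=1e-9)

    def test_single_termination_gets_all(self):
        tree = chain_tree([1e-2, 1e-2])
        mass = assign_terminal_mass_transfer(tree, 0.0141)
        assert list(mass.values()) == [pytest.approx(0.0141)]

    def test_total_is_normalized(self, expanded_trees):
        art, _ = expanded_trees
        mass = assign_terminal_mass_transfer(art, 0.0141,
                                             [0.4, 0.4, 0.2])
        assert sum(mass.values()) == pytest.approx(0.0141, rel=1e-12)

    def test_no_terminations_errors(self):
        tree = vp.VesselTree([[0, 0, 0], [1e-2, 0, 0]], [(0, 1)],
                             boundary_nodes=[0, 1])
        with pytest.raises(TopologyError):
            assign_terminal_mass_transfer(tree, 0.0141)

    def test_per_inlet_subtree_shares(self, seed_trees):
        """With a 40/40/20 split each inlet's subtree drains its share."""
        art, _ = seed_trees
        mass = assign_terminal_mass_transfer(art, 0.0141, [0.4, 0.4, 0.2])
        # seed tree: 3 disjoint subtrees of 2 terminations each
        by_subtree = {}
        for si, m in mass.items():
            root = art.segments[si].a // 4  # 4 nodes per anchor subtree
            by_subtree[root] = by_subtree.get(root, 0.0) + m
        shares = sorted(v / 0.0141 for v in by_subtree.values())
        assert shares == pytest.approx([0.2, 0.4, 0.4], rel=1e-9)


class TestVesselFlows:
    def test_y_tree_symmetric_split(self):
        tree = y_tree()
        mass = assign_terminal_mass_transfer(tree, 0.0141)
        vp.solve_vessel_flows(tree, {0: 0.0141}, mass)
        flows = sorted(s.flow for s in tree.segments)
        assert flows[0] == pytest.approx(0.00705)
        assert flows[1] == pytest.approx(0.00705)
        assert flows[2] == pytest.approx(0.0141)

    def test_chain_carries_full_flow(self):
        tree = chain_tree([1e-2, 1e-2, 1e-2])
        mass = assign_terminal_mass_transfer(tree, 0.0141)
        vp.solve_vessel_flows(tree, {0: 0.0141}, mass)
        assert all(s.flow == pytest.approx(0.0141) for s in tree.segments)

    def test_flows_match_downstream_sum_oracle(self):
        """Edge flows equal the brute-force sum of terminal draws below."""
        rng = np.random.default_rng(0)
        # random tree: attach each new node to a random existing node
        nodes = [np.zeros(3)]
        parents = []
        for i in range(1, 40):
            p = int(rng.integers(0, i))
            parents.append(p)
            nodes.append(nodes[p] + rng.normal(scale=5e-3, size=3))
        tree = vp.VesselTree(nodes, [(p, i + 1) for i, p in enumerate(parents)],
                             boundary_nodes=[0])
        mass = assign_terminal_mass_transfer(tree, 0.0141)
        vp.solve_vessel_flows(tree, {0: 0.0141}, mass)

        term_nodes = tree.termination_nodes()
        draw = np.zeros(tree.n_nodes)
        for si, m in mass.items():
            draw[term_nodes[si]] = m
        # oracle: children sets by walking parent links
        children = {i: [] for i in range(tree.n_nodes)}
        for i, p in enumerate(parents):
            children[p].append(i + 1)

        def subtree_draw(u):
            return draw[u] + sum(subtree_draw(c) for c in children[u])

        for s in tree.segments:
            child = s.b if s.b != 0 and s.a in (0, *parents) else s.a
            # the downstream endpoint of each oriented segment is s.b
            assert s.flow == pytest.approx(subtree_draw(s.b), rel=1e-12)
            assert s.flow >= 0

    def test_unbalanced_boundary_errors(self):
        tree = y_tree()
        mass = assign_terminal_mass_transfer(tree, 0.0141)
        with pytest.raises(ConservationError):
            vp.solve_vessel_flows(tree, {0: 0.001}, mass)

    def test_venous_orientation_toward_outlet(self):
        tree = y_tree(side="venous")
        mass = assign_terminal_mass_transfer(tree, 0.0141)
        vp.solve_vessel_flows(tree, {0: 0.0141}, mass)
        # the trunk segment must flow into the outlet node 0
        trunk = [s for s in tree.segments if 0 in (s.a, s.b)][0]
        assert trunk.b == 0
        assert trunk.flow == pytest.approx(0.0141)


class TestBreakCycles:
    def test_drops_back_edge_and_logs(self, caplog):
        nodes = [[0, 0, 0], [1e-2, 0, 0], [1e-2, 1e-2, 0], [0, 1e-2, 0]]
        tree = vp.VesselTree(
            nodes, [(0, 1), (1, 2), (2, 3), (3, 0)], boundary_nodes=[0]
        )
        with caplog.at_level(logging.WARNING):
            cut = vp.break_cycles(tree)
        assert len(cut.segments) == 3
        assert any("back-edge" in r.message for r in caplog.records)

    def test_acyclic_tree_unchanged(self, seed_trees):
        art, _ = seed_trees
        cut = vp.break_cycles(art)
        assert len(cut.segments) == len(art.segments)


class TestPorousConductance:
    def test_grey_matter_value(self, params):
        """Carman-Kozeny conductance of a pure grey voxel at defaults."""
        frac = np.zeros((3, 3, 3, 5))
        frac[..., 0] = 1.0
        dom = vp.build_domain(vp.TissueMap(frac, 3e-3), params)
        G = vp.porous_conductance(dom, params)
        expected = 1050.0 * 0.0672 * 3e-3 * np.pi * (10e-6) ** 2 / (
            32 * 3.5e-3 * 1.6
        )
        assert G[1, 1, 1] == pytest.approx(expected)
        assert G[1, 1, 1] == pytest.approx(3.71e-10, rel=2e-3)

    def test_doubling_tortuosity_halves_G(self, small_domain, params):
        g1 = vp.porous_conductance(small_domain, params)
        g2 = vp.porous_conductance(
            small_domain, params.with_updates(tortuosity=3.2)
        )
        m = small_domain.brain_mask
        assert np.allclose(g2[m], g1[m] / 2)

    def test_zero_outside_brain(self, small_domain, params):
        G = vp.porous_conductance(small_domain, params)
        assert np.all(G[~small_domain.brain_mask] == 0)


def _two_voxel_domain():
    shape = (2, 1, 1)
    ones = np.ones(shape)
    mask = np.ones(shape, dtype=bool)
    return vp.PorousDomain(
        voxel_edge=3e-3, brain_mask=mask, core_mask=~mask, tissue_mask=mask,
        surface_mask=np.zeros(shape, dtype=bool), rho_c=ones, conductivity=ones,
        q_gen=np.zeros(shape), perfusion_vol=ones, perfusion_clinical=ones,
        eps3=ones * 0.05, eps2=ones * 0.95,
    )


class TestPorousPressure:
    def test_two_voxel_closed_form(self):
        """Source/sink pair: dP = m / G_face and the face carries m."""
        dom = _two_voxel_domain()
        G = np.full(dom.grid_shape, 2e-10)
        m = 1e-5
        src = np.array([m, -m]).reshape(dom.grid_shape)
        P, q = solve_porous_pressure(dom, G, src)
        g_face = 2e-10  # harmonic mean of equal values
        assert P[0, 0, 0] - P[1, 0, 0] == pytest.approx(m / g_face, rel=1e-12)
        assert q[0][0, 0, 0] == pytest.approx(m, rel=1e-12)

    def test_zero_sources_uniform(self):
        dom = _two_voxel_domain()
        G = np.full(dom.grid_shape, 2e-10)
        P, q = solve_porous_pressure(dom, G, np.zeros(dom.grid_shape))
        assert np.allclose(P, 0)
        assert all(np.allclose(qi, 0) for qi in q)

    def test_velocity_invariant_under_G_rescaling(
        self, flow_solution, small_domain, params
    ):
        """U3 is exactly invariant when G is uniformly rescaled (P ~ 1/k);
        this is why capillary diameter and tortuosity barely matter."""
        _, _, flow = flow_solution
        net = flow.arterial_sources - flow.venous_sinks
        P1, q1 = solve_porous_pressure(small_domain, flow.conductance, net)
        P2, q2 = solve_porous_pressure(small_domain, flow.conductance * 7.3, net)
        m = flow.conductance > 0
        assert np.allclose(P2[m] * 7.3, P1[m], rtol=1e-9)
        for a, b in zip(q1, q2):
            assert np.allclose(a, b, atol=1e-18 + 1e-9 * np.abs(a).max())

    def test_unbalanced_sources_error(self):
        dom = _two_voxel_domain()
        G = np.full(dom.grid_shape, 2e-10)
        src = np.array([1e-5, 0.0]).reshape(dom.grid_shape)
        with pytest.raises(ConservationError):
            solve_porous_pressure(dom, G, src)


class TestFullFlowSolve:
    def test_global_mass_conservation(self, flow_solution, total_flow):
        art, ven, flow = flow_solution
        assert flow.arterial_sources.sum() == pytest.approx(
            total_flow, rel=1e-12
        )
        assert flow.venous_sinks.sum() == pytest.approx(total_flow, rel=1e-12)
        assert sum(flow.arterial_terminal_mass.values()) == pytest.approx(
            total_flow, rel=1e-12
        )

    def test_divergence_matches_sources(self, flow_solution, small_domain,
                                        total_flow):
        _, _, flow = flow_solution
        div = porous_divergence(flow.face_flux, small_domain.grid_shape)
        net = flow.arterial_sources - flow.venous_sinks
        assert np.abs(div - net).max() <= 1e-10 * total_flow

    def test_all_segment_flows_positive(self, flow_solution):
        art, ven, _ = flow_solution
        assert all(s.flow > 0 for s in art.segments)
        assert all(s.flow > 0 for s in ven.segments)

    def test_diameters_assigned_and_monotone(self, flow_solution):
        art, _, _ = flow_solution
        for s in art.segments:
            assert s.diameter == pytest.approx(
                float(vp.diameter_from_flow(s.flow))
            )

    def test_mass_on_no_flow_voxel_rejected(self, small_domain, params):
        G = vp.porous_conductance(small_domain, params)
        src = np.zeros(small_domain.grid_shape)
        out = np.argwhere(~small_domain.brain_mask)[0]
        src[tuple(out)] = 1e-5
        src[tuple(np.argwhere(small_domain.brain_mask)[0])] = -1e-5
        with pytest.raises(ConservationError):
            solve_porous_pressure(small_domain, G, src)

    def test_sources_split_over_intersected_brain_voxels(
        self, flow_solution, small_domain
    ):
        art, _, flow = flow_solution
        rebuilt = terminal_sources_to_voxels(
            art, flow.arterial_terminal_mass, small_domain
        )
        assert np.allclose(rebuilt, flow.arterial_sources)
        assert np.all(rebuilt[~small_domain.brain_mask] == 0)
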