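"""Blood flow: 1D vessel-network mass balance and 3D porous Darcy solve.

Blood enters through arterial inlets, travels down the arterial tree,
and crosses into the porous capillary domain at branch terminations at
rates proportional to termination length (M ~ L_BT). It percolates
through the capillary bed, driven by the pressure field of a discrete
conservation law with Carman-Kozeny conductances, and is withdrawn at
venous terminations, collected by the venous tree and removed at the
outlets. Total mass is conserved exactly by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .geometry import PorousDomain
from .params import PhysicalParams
from .vasculature import Segment, VesselTree, assign_diameters, rasterize_segments

logger = logging.getLogger(__name__)

#: Default adult total cerebral inflow, kg/s (14.1 g/s).
TOTAL_INLET_FLOW_ADULT = 0.0141
#: Neonatal total inflow, kg/s (3.1 g/s).
TOTAL_INLET_FLOW_NEONATAL = 0.0031
#: Arterial inlet split: left carotid, right carotid, basilar.
INLET_SPLIT = (0.4, 0.4, 0.2)
#: Venous outlet split: the two transverse sinuses.
OUTLET_SPLIT = (0.5, 0.5)


class TopologyError(ValueError):
    """Tree topology cannot support the requested flow solve."""


class ConservationError(ValueError):
    """Boundary flows and terminal mass transfer do not balance."""


@dataclass
class FlowField:
    """Solved flow state shared by the arterial, porous and venous domains."""

    arterial_terminal_mass: dict = field(default_factory=dict)  # seg -> kg/s
    venous_terminal_mass: dict = field(default_factory=dict)  # seg -> kg/s
    arterial_sources: np.ndarray = None  # per-voxel M_1->3, kg/s
    venous_sinks: np.ndarray = None  # per-voxel M_3->4, kg/s
    conductance: np.ndarray = None  # per-voxel G, m s
    pressure: np.ndarray = None  # Pa
    face_flux: tuple = None  # (qx, qy, qz) interior-face mass flux, kg/s

    def face_velocity(self, params: PhysicalParams, voxel_edge: float) -> tuple:
        """Porous face velocities U3 = q / (rho_b l^2), m/s."""
        denom = params.blood_density * voxel_edge**2
        return tuple(q / denom for q in self.face_flux)


# -- cycle breaking -------------------------------------------------------


def break_cycles(tree: VesselTree) -> VesselTree:
    """Reduce a network to a spanning tree rooted at its boundary nodes.

    Anastomoses such as the circle of Willis make the node mass balance
    underdetermined, so back-edges are dropped: a breadth-first search
    from the boundary nodes keeps the first-listed edge reaching each
    node. Dropped edges are logged loudly.
    """
    tree.validate_connectivity()
    adj = tree.adjacency()
    keep = []
    seen = set(tree.boundary_nodes[:1] or [0])
    queue = list(seen)
    # multi-source BFS: start all boundary nodes at once
    seen = set(tree.boundary_nodes)
    queue = sorted(seen)
    while queue:
        u = queue.pop(0)
        for si, v in sorted(adj[u]):
            if v not in seen:
                seen.add(v)
                keep.append(si)
                queue.append(v)
    dropped = sorted(set(range(len(tree.segments))) - set(keep))
    if dropped:
        logger.warning(
            "break_cycles: dropping %d back-edge segment(s) %s to obtain a "
            "spanning tree", len(dropped), dropped[:10],
        )
    segs = [tree.segments[i] for i in sorted(keep)]
    out = VesselTree(
        tree.nodes,
        [Segment(s.a, s.b, s.diameter, s.flow, list(s.voxels)) for s in segs],
        side=tree.side,
        boundary_nodes=list(tree.boundary_nodes),
    )
    return out


# -- terminal mass transfer ----------------------------------------------


def assign_terminal_mass_transfer(
    tree: VesselTree,
    total_flow: float,
    boundary_fractions=None,
) -> dict:
    """Distribute the total inter-domain mass transfer over terminations.

    Each branch termination receives mass transfer proportional to its
    segment length (M ~ L_BT); all other segments carry none. When
    ``boundary_fractions`` prescribes per-inlet (or per-outlet) shares,
    terminations are grouped by their nearest boundary node in tree-hop
    distance and the length-proportional rule is normalized within each
    group so every boundary node's subtree drains exactly its share.
    """
    if total_flow <= 0:
        raise ValueError("total_flow must be positive")
    term = tree.termination_segments()
    if not term:
        raise TopologyError("tree has no branch terminations")

    if boundary_fractions is None:
        groups = {None: term}
        shares = {None: 1.0}
    else:
        fracs = list(boundary_fractions)
        if len(fracs) != len(tree.boundary_nodes):
            raise ValueError("one fraction per boundary node required")
        if not np.isclose(sum(fracs), 1.0):
            raise ValueError("boundary fractions must sum to 1")
        label = _nearest_boundary_labels(tree)
        term_nodes = tree.termination_nodes()
        groups = {b: [] for b in range(len(tree.boundary_nodes))}
        for si in term:
            groups[label[term_nodes[si]]].append(si)
        shares = dict(enumerate(fracs))
        empty = [b for b, g in groups.items() if not g and shares[b] > 0]
        if empty:
            raise TopologyError(
                f"boundary node(s) {[tree.boundary_nodes[b] for b in empty]} "
                f"have no terminations in their subtree"
            )

    mass = {}
    for key, members in groups.items():
        if not members:
            continue
        lengths = np.array([tree.segment_length(tree.segments[i]) for i in members])
        weights = lengths / lengths.sum()
        for si, w in zip(members, weights):
            mass[si] = float(total_flow * shares[key] * w)
    return mass


def _nearest_boundary_labels(tree: VesselTree) -> np.ndarray:
    """Label every node with its nearest boundary node (hop distance)."""
    adj = tree.adjacency()
    label = np.full(tree.n_nodes, -1, dtype=int)
    queue = []
    for bi, node in enumerate(tree.boundary_nodes):
        label[node] = bi
        queue.append(node)
    while queue:
        u = queue.pop(0)
        for _, v in adj[u]:
            if label[v] == -1:
                label[v] = label[u]
                queue.append(v)
    if np.any(label == -1):
        raise TopologyError("nodes unreachable from any boundary node")
    return label


# -- vessel-network flow --------------------------------------------------


def solve_vessel_flows(
    tree: VesselTree,
    boundary_flows,
    terminal_mass: dict,
) -> VesselTree:
    """Solve per-segment mass flows on an acyclic tree.

    ``boundary_flows`` maps boundary node -> prescribed flow magnitude
    (kg/s): inflow for arterial trees, outflow for venous. Terminal mass
    transfer leaves the arterial tree (or enters the venous tree) at the
    termination nodes. Node mass balance determines every segment flow
    uniquely; segments are re-oriented so flow runs from ``a`` to ``b``
    with non-negative magnitude.
    """
    if isinstance(boundary_flows, (list, tuple, np.ndarray)):
        boundary_flows = dict(zip(tree.boundary_nodes, boundary_flows))
    total_boundary = sum(boundary_flows.values())
    total_mass = sum(terminal_mass.values())
    if abs(total_boundary - total_mass) > 1e-9 * max(total_boundary, 1e-30):
        raise ConservationError(
            f"boundary flow {total_boundary:.6g} != terminal mass "
            f"{total_mass:.6g} kg/s"
        )

    sign = 1.0 if tree.side == "arterial" else -1.0
    injection = np.zeros(tree.n_nodes)
    for node, f in boundary_flows.items():
        injection[node] += sign * f
    term_nodes = tree.termination_nodes()
    for si, m in terminal_mass.items():
        injection[term_nodes[si]] -= sign * m

    adj = tree.adjacency()
    n_edges = len(tree.segments)
    if n_edges != tree.n_nodes - len(tree.connected_components()):
        raise TopologyError("tree contains cycles; run break_cycles first")

    # root each component at its first boundary node; post-order accumulation
    parent_edge = np.full(tree.n_nodes, -1, dtype=int)
    parent = np.full(tree.n_nodes, -1, dtype=int)
    order = []
    visited = np.zeros(tree.n_nodes, dtype=bool)
    for root in tree.boundary_nodes:
        if visited[root]:
            continue
        visited[root] = True
        stack = [root]
        while stack:
            u = stack.pop()
            order.append(u)
            for si, v in adj[u]:
                if not visited[v]:
                    visited[v] = True
                    parent[v] = u
                    parent_edge[v] = si
                    stack.append(v)
    if not np.all(visited):
        raise TopologyError("unreachable nodes in tree")

    subtree = injection.copy()
    for u in reversed(order):
        if parent[u] != -1:
            subtree[parent[u]] += subtree[u]

    # edge flow: net injection accumulated below flows up toward the root;
    # arterial trees send supply down, so the flow direction is parent->child
    # when the child's subtree is a net sink (subtree < 0).
    for child in range(tree.n_nodes):
        si = parent_edge[child]
        if si < 0:
            continue
        s = tree.segments[si]
        f = subtree[child]  # kg/s flowing child -> parent
        if f >= 0:
            frm, to = child, parent[child]
        else:
            frm, to = parent[child], child
            f = -f
        s.a, s.b = frm, to
        s.flow = float(f)
    return tree


# -- porous domain --------------------------------------------------------


def termination_voxel_shares(
    tree: VesselTree, terminal_mass: dict, domain: PorousDomain
) -> dict:
    """Voxel share list per termination: ``{seg: [(voxel, fraction), ...]}``.

    Each termination's mass transfer is split equally (1/N) over its
    intersected voxels inside the brain mask, which is the porous flow
    domain. A termination whose voxels all fall outside the brain (it
    can graze the brain edge) is snapped to the nearest brain voxel so
    mass closure is preserved.
    """
    term_nodes = tree.termination_nodes()
    brain_idx = None
    shares = {}
    for si in terminal_mass:
        seg = tree.segments[si]
        if not seg.voxels:
            raise TopologyError(f"segment {si} not rasterized")
        brain_vox = [v for v in seg.voxels if domain.brain_mask[v]]
        if not brain_vox:
            if brain_idx is None:
                brain_idx = np.argwhere(domain.brain_mask)
            node = tree.nodes[term_nodes[si]]
            centers = (brain_idx + 0.5) * domain.voxel_edge
            nearest = brain_idx[np.argmin(((centers - node) ** 2).sum(axis=1))]
            brain_vox = [tuple(int(c) for c in nearest)]
        w = 1.0 / len(brain_vox)
        shares[si] = [(v, w) for v in brain_vox]
    return shares


def terminal_sources_to_voxels(
    tree: VesselTree, terminal_mass: dict, domain: PorousDomain
) -> np.ndarray:
    """Per-voxel mass transfer map from the termination shares."""
    out = np.zeros(domain.grid_shape)
    for si, vox_shares in termination_voxel_shares(tree, terminal_mass, domain).items():
        m = terminal_mass[si]
        for v, w in vox_shares:
            out[v] += m * w
    return out


def porous_conductance(domain: PorousDomain, params: PhysicalParams) -> np.ndarray:
    """Carman-Kozeny voxel conductance G = rho_b eps3 l pi D_c^2/(32 mu_b tau).

    Zero outside the brain and wherever the blood volume fraction
    vanishes (no-flow voxels).
    """
    G = (
        params.blood_density
        * domain.eps3
        * domain.voxel_edge
        * np.pi
        * params.capillary_diameter**2
        / (32.0 * params.blood_viscosity * params.tortuosity)
    )
    G[~domain.brain_mask] = 0.0
    return G


def _face_conductances(G: np.ndarray) -> tuple:
    """Harmonic-mean conductance on interior faces along each axis."""
    faces = []
    for ax in range(3):
        a = np.moveaxis(G, ax, 0)[:-1]
        b = np.moveaxis(G, ax, 0)[1:]
        s = a + b
        f = np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)
        faces.append(np.moveaxis(f, 0, ax))
    return tuple(faces)


def solve_porous_pressure(
    domain: PorousDomain,
    G: np.ndarray,
    sources: np.ndarray,
    rtol: float = 1e-12,
) -> tuple:
    """Solve the discrete porous conservation law for pressure.

    ``sources`` is the per-voxel net mass injection M_1->3 - M_3->4
    (kg/s). The face flux between neighboring voxels is G_f (P_i - P_j)
    with G_f the harmonic mean of the voxel conductances; the outer
    brain boundary is no-flux, and one voxel per connected flow
    component is pinned to P = 0. Returns ``(P, (qx, qy, qz))`` with q
    the interior-face mass fluxes in kg/s.

    Raises a ``ConservationError`` naming the component if any connected
    flow component carries unbalanced sources.
    """
    flow_mask = G > 0
    scale = np.abs(sources).sum() or 1.0
    if np.any(np.abs(sources[~flow_mask]) > 1e-14 * scale):
        raise ConservationError("mass sources placed on no-flow voxels")

    labels, n_comp = ndimage.label(flow_mask)
    for comp in range(1, n_comp + 1):
        imbalance = sources[labels == comp].sum()
        if abs(imbalance) > 1e-10 * scale:
            raise ConservationError(
                f"flow component {comp} has unbalanced sources "
                f"({imbalance:.3e} kg/s)"
            )

    shape = domain.grid_shape
    idx = -np.ones(shape, dtype=int)
    flat = np.flatnonzero(flow_mask.ravel())
    idx.ravel()[flat] = np.arange(flat.size)
    n = flat.size
    if n == 0:
        return np.zeros(shape), tuple(
            np.zeros((shape[0] - (ax == 0), shape[1] - (ax == 1),
                      shape[2] - (ax == 2))) for ax in range(3)
        )

    Gf = _face_conductances(G)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for ax in range(3):
        f = Gf[ax]
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        i_lo = idx[tuple(sl_lo)].ravel()
        i_hi = idx[tuple(sl_hi)].ravel()
        fv = f.ravel()
        ok = (i_lo >= 0) & (i_hi >= 0) & (fv > 0)
        diag += np.bincount(i_lo[ok], weights=fv[ok], minlength=n)
        diag += np.bincount(i_hi[ok], weights=fv[ok], minlength=n)
        rows.extend([i_lo[ok], i_hi[ok]])
        cols.extend([i_hi[ok], i_lo[ok]])
        vals.extend([-fv[ok], -fv[ok]])
    rows = np.concatenate([np.arange(n)] + rows)
    cols = np.concatenate([np.arange(n)] + cols)
    vals = np.concatenate([diag] + vals)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    b = sources[flow_mask].astype(float)

    # pin one reference voxel per component to P = 0
    for comp in range(1, n_comp + 1):
        ref = idx[tuple(np.argwhere(labels == comp)[0])]
        A = A.tolil() if comp == 1 else A
        A.rows[ref], A.data[ref] = [ref], [1.0]
        b[ref] = 0.0
    A = A.tocsr()
    p = spla.spsolve(A, b)

    P = np.zeros(shape)
    P[flow_mask] = p
    qs = []
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        q = Gf[ax] * (P[tuple(sl_lo)] - P[tuple(sl_hi)])
        q[(~flow_mask[tuple(sl_lo)]) | (~flow_mask[tuple(sl_hi)])] = 0.0
        qs.append(q)
    return P, tuple(qs)


def porous_divergence(face_flux: tuple, shape) -> np.ndarray:
    """Per-voxel net outflow implied by the face fluxes (kg/s)."""
    div = np.zeros(shape)
    for ax, q in enumerate(face_flux):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        div[tuple(sl_lo)] += q
        div[tuple(sl_hi)] -= q
    return div


# -- one-call driver ------------------------------------------------------


def solve_flow(
    arterial: VesselTree,
    venous: VesselTree,
    domain: PorousDomain,
    params: PhysicalParams = None,
    total_flow: float = TOTAL_INLET_FLOW_ADULT,
    inlet_split=INLET_SPLIT,
    outlet_split=OUTLET_SPLIT,
) -> tuple:
    """Full flow solution: vessel flows, diameters and porous pressure.

    Returns ``(arterial, venous, FlowField)`` where the trees are
    cycle-broken, rasterized, flow-solved and diameter-assigned copies.
    """
    params = params or PhysicalParams()
    field_ = FlowField()
    trees = {}
    for tree, split, key in (
        (arterial, inlet_split, "arterial"),
        (venous, outlet_split, "venous"),
    ):
        t = break_cycles(tree)
        rasterize_segments(t, domain)
        split = list(split)[: len(t.boundary_nodes)]
        mass = assign_terminal_mass_transfer(t, total_flow, split)
        flows = dict(zip(t.boundary_nodes, np.asarray(split) * total_flow))
        solve_vessel_flows(t, flows, mass)
        assign_diameters(t)
        trees[key] = t
        if key == "arterial":
            field_.arterial_terminal_mass = mass
        else:
            field_.venous_terminal_mass = mass

    field_.arterial_sources = terminal_sources_to_voxels(
        trees["arterial"], field_.arterial_terminal_mass, domain
    )
    field_.venous_sinks = terminal_sources_to_voxels(
        trees["venous"], field_.venous_terminal_mass, domain
    )
    field_.conductance = porous_conductance(domain, params)
    net = field_.arterial_sources - field_.venous_sinks
    field_.pressure, field_.face_flux = solve_porous_pressure(
        domain, field_.conductance, net
    )
    return trees["arterial"], trees["venous"], field_


def export_flow_csv(tree: VesselTree, path):
    """Per-segment table (endpoints, length, diameter, flow) as CSV."""
    import pandas as pd

    rows = []
    for i, s in enumerate(tree.segments):
        rows.append(
            {
                "segment": i,
                "node_from": s.a,
                "node_to": s.b,
                "length_m": tree.segment_length(s),
                "diameter_m": s.diameter,
                "flow_kg_s": s.flow,
                "n_voxels": s.n_voxels,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
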