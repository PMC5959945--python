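"""Steady-state coupled energy balance of the vascular-porous model.

Four temperature domains are solved simultaneously: arterial vessel
nodes (1), porous tissue (2), porous capillary blood (3) and venous
vessel nodes (4). At the capillary level blood equilibrates with tissue
essentially instantly, so T2 = T3 inside the brain; the two balances are
summed per brain voxel (algebraic elimination) rather than coupled by a
large penalty, which keeps the system well conditioned. Outside the
brain, tissue follows the classical Pennes perfusion-sink balance
against the arterial inlet temperature.

Discretization: second-order central differences for conduction,
first-order upwind advection along vessel segments and across porous
voxel faces. Counter-current heat exchange in the capillary bed is
modelled by flow reversal: the net porous velocity U3 is split into a
forward stream C_R*U3 and a reverse stream -(C_R-1)*U3, each upwinded
separately. C_R = 1 recovers plain upwind advection exactly.

Inter-domain heat transfer follows laminar Newtonian tube flow,
beta = eps * Nu * K_b * pi * L / N per intersected voxel (the vessel
diameter cancels), split equally over the N voxels a segment crosses.
Mass transfer enthalpy is applied in the energy-conserving orientation
(the incoming stream contributes c_b*M*(T_source - T_local)); a switch
reproduces the anti-conservative orientation for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .flow import FlowField, termination_voxel_shares
from .geometry import PorousDomain
from .params import PhysicalParams
from .vasculature import VesselTree

#: Default boundary temperatures (degC).
T_SCALP_WARM = 33.5
T_SCALP_COLD = 10.0


class AssemblyError(ValueError):
    """The linear system could not be assembled (isolated unknowns...)."""


class SolverError(RuntimeError):
    """The assembled system failed to solve to tolerance."""


@dataclass
class TemperatureField:
    """Solved temperatures for tissue voxels and vessel nodes (degC)."""

    tissue: np.ndarray  # grid; NaN outside the head
    arterial_nodes: np.ndarray = None
    venous_nodes: np.ndarray = None
    t_scalp: float = np.nan
    t_arterial: float = np.nan

    def mean_over(self, mask: np.ndarray) -> float:
        """Volume-weighted mean temperature over a voxel mask."""
        return float(np.nanmean(self.tissue[mask]))


def heat_coupling(
    tree: VesselTree, seg_index: int, domain: PorousDomain, params: PhysicalParams
) -> dict:
    """Per-voxel inter-domain heat-transfer coefficients of one segment.

    Returns ``{voxel: (beta_tissue, beta_blood)}`` in W/degC, where
    beta_tissue couples the vessel to domain 2 (weight eps2) and
    beta_blood to domain 3 (weight eps3). The segment total
    Nu*K_b*pi*L is divided equally over its N intersected voxels; air
    voxels receive no exchange.
    """
    seg = tree.segments[seg_index]
    if seg.n_voxels == 0:
        raise ValueError(f"segment {seg_index} not rasterized")
    base = (
        params.nusselt
        * params.blood_conductivity
        * np.pi
        * tree.segment_length(seg)
        / seg.n_voxels
    )
    out = {}
    for v in seg.voxels:
        if not domain.tissue_mask[v]:
            continue
        out[v] = (base * domain.eps2[v], base * domain.eps3[v])
    return out


@dataclass
class SteadySystem:
    """Assembled sparse steady-state system A T = b with its index maps."""

    A: sp.csr_matrix
    b: np.ndarray
    vox_index: np.ndarray  # grid -> unknown index (-1 outside head)
    n_vox: int
    n_art: int
    n_ven: int
    domain: PorousDomain
    arterial: VesselTree = None
    venous: VesselTree = None
    t_scalp: float = np.nan
    t_arterial: float = np.nan


class _Builder:
    """COO accumulator that silently drops entries on Dirichlet rows."""

    def __init__(self, n: int):
        self.n = n
        self.rows, self.cols, self.vals = [], [], []
        self.b = np.zeros(n)
        self.dirichlet = np.zeros(n, dtype=bool)
        self.dirichlet_vals = np.zeros(n)

    def set_dirichlet(self, idx, value):
        self.dirichlet[idx] = True
        self.dirichlet_vals[idx] = value

    def add(self, rows, cols, vals):
        rows = np.atleast_1d(np.asarray(rows, dtype=int))
        cols = np.atleast_1d(np.asarray(cols, dtype=int))
        vals = np.broadcast_to(np.atleast_1d(np.asarray(vals, float)), rows.shape)
        keep = ~self.dirichlet[rows]
        self.rows.append(rows[keep])
        self.cols.append(cols[keep])
        self.vals.append(vals[keep])

    def add_rhs(self, rows, vals):
        rows = np.atleast_1d(np.asarray(rows, dtype=int))
        vals = np.broadcast_to(np.atleast_1d(np.asarray(vals, float)), rows.shape)
        np.subtract.at(self.b, rows[~self.dirichlet[rows]], vals[~self.dirichlet[rows]])

    def add_exchange(self, i, j, coeff):
        """Term +coeff*(T_j - T_i) in row i."""
        self.add([i, i], [j, i], [coeff, -coeff])

    def finalize(self) -> tuple:
        d = np.flatnonzero(self.dirichlet)
        self.rows.append(d)
        self.cols.append(d)
        self.vals.append(np.ones(d.size))
        self.b[d] = self.dirichlet_vals[d]
        A = sp.csr_matrix(
            (
                np.concatenate(self.vals),
                (np.concatenate(self.rows), np.concatenate(self.cols)),
            ),
            shape=(self.n, self.n),
        )
        empty = np.flatnonzero(np.abs(A).sum(axis=1).A1 == 0)
        if empty.size:
            raise AssemblyError(f"zero rows for unknowns {empty[:5].tolist()}")
        return A, self.b


def _face_harmonic(field: np.ndarray, mask: np.ndarray, ax: int) -> np.ndarray:
    """Harmonic-mean field on interior faces; zero at air faces."""
    a = np.moveaxis(field, ax, 0)[:-1]
    b = np.moveaxis(field, ax, 0)[1:]
    ma = np.moveaxis(mask, ax, 0)[:-1]
    mb = np.moveaxis(mask, ax, 0)[1:]
    s = a + b
    f = np.where(ma & mb & (s > 0), 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)
    return np.moveaxis(f, 0, ax)


def _lo_hi_face_indices(idx: np.ndarray, ax: int) -> tuple:
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[ax] = slice(0, -1)
    sl_hi[ax] = slice(1, None)
    return idx[tuple(sl_lo)].ravel(), idx[tuple(sl_hi)].ravel()


def assemble_steady_system(
    domain: PorousDomain,
    arterial: VesselTree,
    venous: VesselTree,
    flow: FlowField,
    params: PhysicalParams,
    t_scalp: float,
    flow_reversal: float = None,
    printed_sign_mode: bool = False,
) -> SteadySystem:
    """Assemble the steady four-domain energy balance as a sparse system.

    Unknowns: one temperature per head voxel (T2 = T3 merged inside the
    brain), one per arterial node, one per venous node. Dirichlet rows
    pin surface voxels to ``t_scalp`` and arterial inlets to the
    arterial temperature; venous outlets close with advective outflow
    (zero diffusion). ``flow_reversal`` is the counter-current constant
    C_R (defaults to the value in ``params``).
    """
    cr = params.flow_reversal if flow_reversal is None else float(flow_reversal)
    cb = params.blood_heat_capacity
    ta = params.arterial_temperature
    shape = domain.grid_shape
    l = domain.voxel_edge
    V = domain.voxel_volume

    vox_index = -np.ones(shape, dtype=int)
    head = domain.tissue_mask
    n_vox = int(head.sum())
    vox_index[head] = np.arange(n_vox)
    n_art = arterial.n_nodes
    n_ven = venous.n_nodes
    art_off, ven_off = n_vox, n_vox + n_art
    n = n_vox + n_art + n_ven
    B = _Builder(n)

    # Dirichlet: scalp surface shell and arterial inlets
    B.set_dirichlet(vox_index[domain.surface_mask], t_scalp)
    for node in arterial.boundary_nodes:
        B.set_dirichlet(art_off + node, ta)
    ven_outlets = set(venous.boundary_nodes)

    # -- voxel conduction (effective conductivity in the brain) ----------
    k_eff = np.where(
        domain.brain_mask,
        domain.eps2 * domain.conductivity + domain.eps3 * params.blood_conductivity,
        domain.conductivity,
    )
    for ax in range(3):
        kf = _face_harmonic(k_eff, head, ax) * l  # W/degC per face
        i_lo, i_hi = _lo_hi_face_indices(vox_index, ax)
        kv = kf.ravel()
        ok = (i_lo >= 0) & (i_hi >= 0) & (kv > 0)
        ilo, ihi, kv = i_lo[ok], i_hi[ok], kv[ok]
        B.add(ilo, ihi, kv)
        B.add(ilo, ilo, -kv)
        B.add(ihi, ilo, kv)
        B.add(ihi, ihi, -kv)

    # -- porous advection with flow reversal -----------------------------
    if flow.face_flux is not None:
        for ax in range(3):
            q = flow.face_flux[ax].ravel()
            i_lo, i_hi = _lo_hi_face_indices(vox_index, ax)
            ok = (q != 0) & (i_lo >= 0) & (i_hi >= 0)
            q, ilo, ihi = q[ok], i_lo[ok], i_hi[ok]
            qp, qm = np.maximum(q, 0.0), np.maximum(-q, 0.0)
            # forward stream C_R*q and reverse stream -(C_R-1)*q,
            # each first-order upwinded
            c_hi = cb * (cr * qp + (cr - 1.0) * qm)  # into hi, from lo
            c_lo = cb * (cr * qm + (cr - 1.0) * qp)  # into lo, from hi
            B.add(ihi, ilo, c_hi)
            B.add(ihi, ihi, -c_hi)
            B.add(ilo, ihi, c_lo)
            B.add(ilo, ilo, -c_lo)

    # -- non-brain perfusion sink and metabolic sources ------------------
    interior = head & ~domain.surface_mask
    perf = interior & ~domain.brain_mask
    rows = vox_index[perf]
    wv = cb * domain.perfusion_vol[perf] * V
    B.add(rows, rows, -wv)
    B.add_rhs(rows, wv * ta)  # +c_b*w*V*T_a constant
    rows = vox_index[interior]
    B.add_rhs(rows, V * domain.q_gen[interior])

    # -- vessel segments: axial conduction, advection, beta exchange -----
    kb = params.blood_conductivity
    for tree, off in ((arterial, art_off), (venous, ven_off)):
        is_ven = tree.side == "venous"
        for si, s in enumerate(tree.segments):
            na, nb = off + s.a, off + s.b
            L = tree.segment_length(s)
            at_outlet = is_ven and (s.a in ven_outlets or s.b in ven_outlets)
            # axial conduction (zero-diffusion closure at venous outlets)
            if s.diameter > 0 and not at_outlet:
                c = kb * np.pi * s.diameter**2 / 4.0 / L
                B.add_exchange(na, nb, c)
                B.add_exchange(nb, na, c)
            # upwind advection a -> b
            if s.flow > 0:
                B.add_exchange(nb, na, cb * s.flow)
            # inter-domain heat exchange, attached to the downstream node
            # (upstream if downstream is an outflow-closure outlet node)
            node = nb if not (is_ven and s.b in ven_outlets) else na
            for vox, (b2, b3) in heat_coupling(tree, si, domain, params).items():
                beta = b2 + b3  # T2 = T3 in the brain; eps3 = 0 outside
                vi = vox_index[vox]
                B.add_exchange(vi, node, beta)
                B.add_exchange(node, vi, beta)

    # -- inter-domain mass-transfer enthalpy -----------------------------
    # conserving orientation: receiver gains c_b*M*(T_source - T_local)
    sgn = -1.0 if printed_sign_mode else 1.0
    for tree, off, mass in (
        (arterial, art_off, flow.arterial_terminal_mass),
        (venous, ven_off, flow.venous_terminal_mass),
    ):
        to_vessel = tree.side == "venous"
        term_nodes = tree.termination_nodes()
        vox_shares = termination_voxel_shares(tree, mass, domain)
        for si, m in mass.items():
            node = off + term_nodes[si]
            for v, w in vox_shares[si]:
                vi = vox_index[v]
                if to_vessel:  # porous blood -> venous node
                    B.add_exchange(node, vi, sgn * cb * m * w)
                else:  # arterial node -> porous blood
                    B.add_exchange(vi, node, sgn * cb * m * w)

    A, b = B.finalize()
    sys_ = SteadySystem(
        A=A,
        b=b,
        vox_index=vox_index,
        n_vox=n_vox,
        n_art=n_art,
        n_ven=n_ven,
        domain=domain,
        arterial=arterial,
        venous=venous,
        t_scalp=t_scalp,
        t_arterial=ta,
    )
    return sys_


def _sparse_solve(A: sp.csr_matrix, b: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Solve A x = b to a relative residual <= rtol.

    An ILU-preconditioned GMRES attempt comes first (the upwind/central
    discretization yields a diagonally dominant M-matrix that ILU
    preconditions very well); if it misses the tolerance, a direct
    sparse LU factorization is used instead.
    """
    A = A.tocsc()
    bnorm = max(np.linalg.norm(b), 1e-300)
    try:
        ilu = spla.spilu(A, drop_tol=1e-5, fill_factor=20)
        M = spla.LinearOperator(A.shape, ilu.solve)
        x, info = spla.gmres(A, b, M=M, rtol=1e-14, atol=0.0, restart=50,
                             maxiter=300)
        if info == 0 and np.linalg.norm(A @ x - b) / bnorm <= rtol:
            return x
    except RuntimeError:
        pass  # singular preconditioner; fall through to direct solve
    x = spla.spsolve(A, b)
    return x


def solve_steady_temperatures(system: SteadySystem) -> TemperatureField:
    """Sparse solve of the assembled system; residual <= 1e-10 relative."""
    A, b = system.A, system.b
    x = _sparse_solve(A, b)
    if not np.all(np.isfinite(x)):
        raise SolverError("non-finite solution; system singular?")
    res = np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300)
    if res > 1e-10:
        raise SolverError(f"relative residual {res:.2e} exceeds 1e-10")
    tissue = np.full(system.domain.grid_shape, np.nan)
    tissue[system.vox_index >= 0] = x[: system.n_vox]
    art = x[system.n_vox : system.n_vox + system.n_art] if system.n_art else None
    ven = x[system.n_vox + system.n_art :] if system.n_ven else None
    return TemperatureField(
        tissue=tissue,
        arterial_nodes=art,
        venous_nodes=ven,
        t_scalp=system.t_scalp,
        t_arterial=system.t_arterial,
    )


def vapor_steady_solve(
    domain: PorousDomain,
    arterial: VesselTree,
    venous: VesselTree,
    flow: FlowField,
    params: PhysicalParams = None,
    t_scalp: float = T_SCALP_WARM,
    flow_reversal: float = None,
    printed_sign_mode: bool = False,
) -> TemperatureField:
    """Assemble and solve the coupled vascular-porous energy balance."""
    params = params or PhysicalParams()
    system = assemble_steady_system(
        domain, arterial, venous, flow, params, t_scalp, flow_reversal,
        printed_sign_mode,
    )
    return solve_steady_temperatures(system)


def pbe_steady_solve(
    domain: PorousDomain,
    params: PhysicalParams = None,
    t_scalp: float = T_SCALP_WARM,
) -> TemperatureField:
    """Steady Pennes bioheat baseline over the whole head.

    Solves K*lap(T) - c_b*w*(T - T_a) + Q_gen = 0 with the scalp shell
    pinned to ``t_scalp``; perfusion acts everywhere, brain included.
    """
    params = params or PhysicalParams()
    cb = params.blood_heat_capacity
    ta = params.arterial_temperature
    shape = domain.grid_shape
    head = domain.tissue_mask
    V = domain.voxel_volume
    l = domain.voxel_edge

    vox_index = -np.ones(shape, dtype=int)
    n_vox = int(head.sum())
    vox_index[head] = np.arange(n_vox)
    B = _Builder(n_vox)
    B.set_dirichlet(vox_index[domain.surface_mask], t_scalp)

    for ax in range(3):
        kf = _face_harmonic(domain.conductivity, head, ax) * l
        i_lo, i_hi = _lo_hi_face_indices(vox_index, ax)
        kv = kf.ravel()
        ok = (i_lo >= 0) & (i_hi >= 0) & (kv > 0)
        ilo, ihi, kv = i_lo[ok], i_hi[ok], kv[ok]
        B.add(ilo, ihi, kv)
        B.add(ilo, ilo, -kv)
        B.add(ihi, ilo, kv)
        B.add(ihi, ihi, -kv)

    interior = head & ~domain.surface_mask
    rows = vox_index[interior]
    wv = cb * domain.perfusion_vol[interior] * V
    B.add(rows, rows, -wv)
    B.add_rhs(rows, wv * ta)
    B.add_rhs(rows, V * domain.q_gen[interior])

    A, b = B.finalize()
    x = _sparse_solve(A, b)
    res = np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300)
    if res > 1e-10:
        raise SolverError(f"relative residual {res:.2e} exceeds 1e-10")
    tissue = np.full(shape, np.nan)
    tissue[head] = x
    return TemperatureField(tissue=tissue, t_scalp=t_scalp, t_arterial=ta)


def energy_budget(
    system: SteadySystem,
    field: TemperatureField,
    flow: FlowField,
    params: PhysicalParams,
) -> dict:
    """Recompute the global steady energy balance from solved fields.

    Channels (W): metabolic generation, inlet advective + conductive
    enthalpy, outlet advective enthalpy, conductive loss through the
    scalp surface, and the non-brain perfusion exchange. At steady state
    generation + inflow = outflow + surface loss + perfusion exchange;
    the returned ``residual_rel`` is the closure error relative to the
    largest channel.
    """
    domain = system.domain
    cb = params.blood_heat_capacity
    ta = params.arterial_temperature
    l = domain.voxel_edge
    V = domain.voxel_volume
    head = domain.tissue_mask
    interior = head & ~domain.surface_mask
    T = field.tissue

    q_met = float((V * domain.q_gen[interior]).sum())
    q_perf = float(
        (
            cb
            * domain.perfusion_vol[interior & ~domain.brain_mask]
            * V
            * (T[interior & ~domain.brain_mask] - ta)
        ).sum()
    )

    # conductive loss through the Dirichlet surface shell
    k_eff = np.where(
        domain.brain_mask,
        domain.eps2 * domain.conductivity + domain.eps3 * params.blood_conductivity,
        domain.conductivity,
    )
    q_surf = 0.0
    Ts = np.where(domain.surface_mask, T, 0.0)
    for ax in range(3):
        kf = _face_harmonic(k_eff, head, ax) * l
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        lo_surf = domain.surface_mask[tuple(sl_lo)]
        hi_surf = domain.surface_mask[tuple(sl_hi)]
        t_lo = T[tuple(sl_lo)]
        t_hi = T[tuple(sl_hi)]
        mixed = lo_surf ^ hi_surf
        with np.errstate(invalid="ignore"):
            flux = kf * (t_lo - t_hi)  # W, positive lo -> hi
        sgn = np.where(hi_surf, 1.0, -1.0)  # positive = into the surface
        q_surf += float(np.nansum(np.where(mixed, sgn * flux, 0.0)))

    # vessel boundary enthalpy
    e_in = 0.0
    inlets = set(system.arterial.boundary_nodes)
    for s in system.arterial.segments:
        if s.a in inlets:
            e_in += cb * s.flow * ta
            if s.diameter > 0:
                L = system.arterial.segment_length(s)
                e_in += (
                    params.blood_conductivity
                    * np.pi
                    * s.diameter**2
                    / 4.0
                    / L
                    * (ta - field.arterial_nodes[s.b])
                )
    e_out = 0.0
    outlets = set(system.venous.boundary_nodes)
    for s in system.venous.segments:
        if s.b in outlets:
            e_out += cb * s.flow * field.venous_nodes[s.b]

    lhs = q_met + e_in
    rhs = e_out + q_surf + q_perf
    scale = max(abs(q_met), abs(e_in), abs(e_out), abs(q_surf), 1e-30)
    return {
        "metabolic_W": q_met,
        "inlet_W": e_in,
        "outlet_W": e_out,
        "surface_W": q_surf,
        "perfusion_W": q_perf,
        "residual_rel": abs(lhs - rhs) / scale,
    }


def save_temperature_nifti(field: TemperatureField, domain: PorousDomain, path):
    """Write the tissue temperature volume as NIfTI (voxel size in mm)."""
    import nibabel as nib

    edge_mm = domain.voxel_edge * 1e3
    affine = np.diag([edge_mm, edge_mm, edge_mm, 1.0])
    img = nib.Nifti1Image(field.tissue.astype(np.float32), affine)
    nib.save(img, path)


def save_vessel_temperatures_csv(tree: VesselTree, node_temps: np.ndarray, path):
    """Per-node vessel temperature table as CSV."""
    import pandas as pd

    pts = tree.node_array()
    pd.DataFrame(
        {
            "node": np.arange(tree.n_nodes),
            "x_m": pts[:, 0],
            "y_m": pts[:, 1],
            "z_m": pts[:, 2],
            "temperature_C": node_temps,
        }
    ).to_csv(path, index=False)
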