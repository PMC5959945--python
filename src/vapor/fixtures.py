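"""Synthetic inputs: a layered head phantom and hand-built seed trees.

The phantom is a set of nested ellipsoids (scalp, bone, CSF, grey shell,
white core) on an isotropic voxel grid. It is deliberately simple -- no
gyrification, ventricles or anatomical asymmetry -- but it exercises all
five tissue classes with analytically known layer volumes, so every
downstream solver can be tested without external imaging data.

Seed vessel trees mimic the topology of imaged cerebral vasculature at
the coarsest level: three arterial inlets (left/right "carotid" and a
"basilar" anchor) and two venous outlets ("transverse sinuses"), each a
short branched tree reaching into the brain layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PorousDomain, TissueMap, build_domain
from .params import TISSUE_CLASSES, PhysicalParams
from .vasculature import Segment, VesselTree


class PhantomSpecError(ValueError):
    """The phantom layering is geometrically impossible."""


@dataclass
class PhantomSpec:
    """Nested-ellipsoid head phantom definition.

    Layer radii are fractions of the head semi-axes, strictly decreasing
    inward in the order scalp, bone, CSF, grey shell, white core. The
    head semi-axes are ``semi_axis_fraction`` times the half-extent of
    the grid in each direction.
    """

    grid_shape: tuple = (40, 48, 40)
    voxel_edge: float = 3e-3  # m
    layer_radii: dict = field(
        default_factory=lambda: {
            "scalp": 1.0,
            "bone": 0.90,
            "csf": 0.80,
            "grey": 0.72,
            "white": 0.45,
        }
    )
    semi_axis_fraction: float = 0.92
    blend: bool = False  # supersampled fractional boundaries

    # anchors, as offsets from center in units of the head semi-axes;
    # all lie inside the brain layer
    arterial_anchors: dict = field(
        default_factory=lambda: {
            "carotid_left": (-0.30, -0.05, -0.25),
            "carotid_right": (0.30, -0.05, -0.25),
            "basilar": (0.0, -0.25, -0.30),
        }
    )
    venous_anchors: dict = field(
        default_factory=lambda: {
            "transverse_left": (-0.25, 0.25, -0.20),
            "transverse_right": (0.25, 0.25, -0.20),
        }
    )

    def __post_init__(self):
        radii = [self.layer_radii[k] for k in ("scalp", "bone", "csf", "grey", "white")]
        if not all(a > b for a, b in zip(radii, radii[1:])):
            raise PhantomSpecError("layer radii must strictly decrease inward")

    @property
    def semi_axes(self) -> np.ndarray:
        half_extent = np.asarray(self.grid_shape) * self.voxel_edge / 2.0
        return self.semi_axis_fraction * half_extent

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * self.voxel_edge / 2.0

    def validate_layer_thickness(self):
        radii = [self.layer_radii[k] for k in ("scalp", "bone", "csf", "grey", "white")]
        min_axis = float(self.semi_axes.min())
        for (hi, lo) in zip(radii, radii[1:]):
            if (hi - lo) * min_axis < self.voxel_edge:
                raise PhantomSpecError(
                    f"layer between radii {hi} and {lo} is thinner than one voxel"
                )

    def anchor_world(self, offset) -> np.ndarray:
        return self.center + np.asarray(offset) * self.semi_axes


def _ellipsoid_radius(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Normalized radius: 1.0 on the head surface."""
    rel = (points - spec.center) / spec.semi_axes
    return np.sqrt((rel**2).sum(axis=-1))


def _classify(r: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Class index per point (0..4 in TISSUE_CLASSES order, -1 = air)."""
    lr = spec.layer_radii
    out = np.full(r.shape, -1, dtype=int)
    out[r <= lr["scalp"]] = TISSUE_CLASSES.index("scalp")
    out[r <= lr["bone"]] = TISSUE_CLASSES.index("bone")
    out[r <= lr["csf"]] = TISSUE_CLASSES.index("csf")
    out[r <= lr["grey"]] = TISSUE_CLASSES.index("grey")
    out[r <= lr["white"]] = TISSUE_CLASSES.index("white")
    return out


def make_phantom_head(spec: PhantomSpec = None) -> TissueMap:
    """Build the layered ellipsoidal head phantom as a tissue map.

    With ``blend=False`` every voxel belongs to a single class at
    fraction 1 (hard boundaries, classified at the voxel center). With
    ``blend=True`` each voxel is supersampled 3x3x3 and fractions are
    the sub-sample class shares, giving linear blending at interfaces.
    Deterministic.
    """
    spec = spec or PhantomSpec()
    spec.validate_layer_thickness()
    shape = spec.grid_shape
    l = spec.voxel_edge
    frac = np.zeros(shape + (len(TISSUE_CLASSES),))

    if spec.blend:
        sub = (np.arange(3) + 0.5) / 3.0
        offsets = np.stack(np.meshgrid(sub, sub, sub, indexing="ij"), -1).reshape(-1, 3)
    else:
        offsets = np.array([[0.5, 0.5, 0.5]])

    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).astype(float)
    for off in offsets:
        pts = (idx + off) * l
        cls = _classify(_ellipsoid_radius(pts, spec), spec)
        for ci in range(len(TISSUE_CLASSES)):
            frac[..., ci] += (cls == ci) / len(offsets)
    return TissueMap(frac, l)


def analytic_layer_volume(spec: PhantomSpec, cls: str) -> float:
    """Exact volume (m^3) of one phantom layer shell."""
    order = ("scalp", "bone", "csf", "grey", "white")
    a, b, c = spec.semi_axes
    full = 4.0 / 3.0 * np.pi * a * b * c
    r_out = spec.layer_radii[cls]
    i = order.index(cls)
    r_in = spec.layer_radii[order[i + 1]] if i + 1 < len(order) else 0.0
    return full * (r_out**3 - r_in**3)


def make_seed_trees(spec: PhantomSpec = None) -> tuple:
    """Hand-built arterial and venous seed trees inside the phantom brain.

    Each boundary anchor sprouts a short Y-shaped subtree reaching into
    the brain layer, so terminal mass transfer, per-inlet flow splits
    and the thermal couplings are all exercised. Deterministic.
    """
    spec = spec or PhantomSpec()
    brain_r = spec.layer_radii["grey"]

    def check_anchor(offset):
        r = float(np.sqrt((np.asarray(offset) ** 2).sum()))
        if r >= brain_r:
            raise PhantomSpecError(f"anchor {offset} outside the brain layer")

    def build(anchors, side):
        nodes, segments, boundary = [], [], []
        for k, (name, off) in enumerate(anchors.items()):
            check_anchor(off)
            off = np.asarray(off, dtype=float)
            root = spec.anchor_world(off)
            # rise toward the brain center, then split into two branches
            stem_tip = spec.anchor_world(off * 0.55 + [0.0, 0.0, 0.12])
            lateral = np.array([0.18, 0.0, 0.0])
            up = np.array([0.0, 0.14, 0.10])
            tip_a = spec.anchor_world(off * 0.35 + lateral * (1 if k % 2 else -1) + up)
            tip_b = spec.anchor_world(off * 0.35 - lateral * (1 if k % 2 else -1) + up)
            base = len(nodes)
            nodes.extend([root, stem_tip, tip_a, tip_b])
            segments.extend(
                [
                    Segment(base, base + 1),
                    Segment(base + 1, base + 2),
                    Segment(base + 1, base + 3),
                ]
            )
            boundary.append(base)
        return VesselTree(nodes, segments, side=side, boundary_nodes=boundary)

    arterial = build(spec.arterial_anchors, "arterial")
    venous = build(spec.venous_anchors, "venous")
    return arterial, venous


def make_2d_rrt_domain(
    perfusion_ratio: float = 4.0,
    shaded_area_fraction: float = 0.5,
    grid: tuple = (50, 50),
    voxel_edge: float = 3e-3,
) -> tuple:
    """Two-region flat domain for demonstrating perfusion-weighted growth.

    A one-voxel-thick grid is split along x into a "shaded" region
    (fraction ``shaded_area_fraction`` of the area, perfusion weight
    ``perfusion_ratio``) and an unshaded region (weight 1). A single
    seed segment runs along the dividing line so both regions are
    equally accessible. Returns ``(domain, seed_tree, boundary_x)``
    where ``boundary_x`` is the world x coordinate of the divide.
    """
    if perfusion_ratio <= 0:
        raise ValueError("perfusion_ratio must be positive")
    nx, ny = grid
    shape = (nx, ny, 1)
    split = int(round(nx * (1.0 - shaded_area_fraction)))
    perf = np.ones(shape)
    perf[split:, :, :] = perfusion_ratio

    ones = np.ones(shape)
    mask = np.ones(shape, dtype=bool)
    domain = PorousDomain(
        voxel_edge=voxel_edge,
        brain_mask=mask,
        core_mask=np.zeros(shape, dtype=bool),
        tissue_mask=mask,
        surface_mask=np.zeros(shape, dtype=bool),
        rho_c=ones * 1e6,
        conductivity=ones * 0.5,
        q_gen=np.zeros(shape),
        perfusion_vol=perf,
        perfusion_clinical=perf,
        eps3=ones * 0.05,
        eps2=ones * 0.95,
    )
    boundary_x = split * voxel_edge
    y0, y1 = 0.2 * ny * voxel_edge, 0.8 * ny * voxel_edge
    z = 0.5 * voxel_edge
    seed = VesselTree(
        [[boundary_x, y0, z], [boundary_x, y1, z]],
        [Segment(0, 1)],
        side="arterial",
        boundary_nodes=[0],
    )
    return domain, seed, boundary_x


def region_segment_counts(tree: VesselTree, boundary_x: float) -> tuple:
    """Generated-segment counts (shaded, unshaded) by midpoint x.

    Counts the segments created by tree expansion — those attaching a
    generated node — classified by midpoint; segments lying on the
    dividing line are skipped. Bookkeeping fragments produced by
    splitting a pre-existing segment at an interior attachment point
    are not new vasculature and are excluded; including them would
    double-count regions where the tree is already dense. For a tree
    without expansion metadata every segment is counted.
    """
    generated = getattr(tree, "generated_nodes", None)
    gen = set(generated) if generated else None
    hi = lo = 0
    for s in tree.segments:
        if gen is not None and s.a not in gen and s.b not in gen:
            continue
        mx = 0.5 * (tree.nodes[s.a][0] + tree.nodes[s.b][0])
        if mx > boundary_x + 1e-12:
            hi += 1
        elif mx < boundary_x - 1e-12:
            lo += 1
    return hi, lo


def make_phantom_domain(
    spec: PhantomSpec = None, params: PhysicalParams = None
) -> PorousDomain:
    """Phantom tissue map -> mixed-property porous domain, in one call."""
    return build_domain(make_phantom_head(spec), params or PhysicalParams())
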