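"""Voxelized head domain: tissue-fraction maps and mixed porous properties.

The head is represented as a regular isotropic voxel grid. Each voxel
carries a fraction of each tissue class (grey matter, white matter, CSF,
bone, scalp); any remainder is air/background. Per-voxel physical
properties are fraction-weighted mixtures of the class values, the brain
mask is the set of voxels that are at least half grey+white matter, and
the core is the set of voxels with more than half white matter.

Coordinate convention: 0-based voxel indices; a voxel's node point is its
center, so world coordinates are ``index * l + l/2`` with ``l`` the voxel
edge length in meters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import nibabel as nib
from scipy import ndimage

from .params import TISSUE_CLASSES, PhysicalParams, perfusion_to_volumetric

#: Any voxel whose summed tissue fraction falls below this is air.
AIR_THRESHOLD = 0.5
#: grey+white fraction at or above this marks a brain voxel.
BRAIN_THRESHOLD = 0.5
#: white fraction strictly above this marks a core voxel.
CORE_WHITE_THRESHOLD = 0.5


class ShapeError(ValueError):
    """Input volumes do not share a common grid."""


class DomainError(ValueError):
    """The domain is degenerate (e.g. empty brain mask)."""


@dataclass
class TissueMap:
    """Per-voxel tissue-class fractions on an isotropic voxel grid.

    Parameters
    ----------
    fractions
        Array of shape ``grid_shape + (5,)`` holding the fraction of each
        class in :data:`~vapor.params.TISSUE_CLASSES` order. Fractions are
        non-negative and sum to at most 1 per voxel; the remainder is air.
    voxel_edge
        Isotropic voxel edge length in meters.
    """

    fractions: np.ndarray
    voxel_edge: float

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 4 or self.fractions.shape[-1] != len(TISSUE_CLASSES):
            raise ShapeError(
                f"fractions must have shape (nx, ny, nz, {len(TISSUE_CLASSES)})"
            )
        if self.voxel_edge <= 0:
            raise ValueError("voxel_edge must be positive")
        if np.any(self.fractions < -1e-12):
            raise ValueError("tissue fractions must be non-negative")
        if np.any(self.fractions > 1 + 1e-9):
            raise ValueError("tissue fractions must be <= 1")
        total = self.fractions.sum(axis=-1)
        if np.any(total > 1 + 1e-6):
            raise ValueError("per-voxel tissue fractions must sum to <= 1")

    @property
    def grid_shape(self) -> tuple:
        return self.fractions.shape[:3]

    def class_fraction(self, name: str) -> np.ndarray:
        return self.fractions[..., TISSUE_CLASSES.index(name)]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (m) of all voxel centers, shape grid+(3,)."""
        l = self.voxel_edge
        grids = np.meshgrid(
            *[(np.arange(n) + 0.5) * l for n in self.grid_shape], indexing="ij"
        )
        return np.stack(grids, axis=-1)


@dataclass
class PorousDomain:
    """Mixed per-voxel physical properties plus masks for the solvers.

    ``perfusion_vol`` is the volumetric perfusion in kg blood/m^3 tissue/s
    (used by the continuum perfusion sink outside the brain);
    ``perfusion_clinical`` keeps the ml/100g/min values for reporting and
    for perfusion-weighted vessel sampling. ``eps3`` is the capillary
    blood volume fraction (zero outside the brain), ``eps2 = 1 - eps3``.
    """

    voxel_edge: float
    brain_mask: np.ndarray
    core_mask: np.ndarray
    tissue_mask: np.ndarray  # non-air voxels (includes brain)
    surface_mask: np.ndarray  # non-air voxels with an air-adjacent face
    rho_c: np.ndarray  # J/m^3/degC
    conductivity: np.ndarray  # W/m/degC
    q_gen: np.ndarray  # W/m^3
    perfusion_vol: np.ndarray  # kg/m^3/s
    perfusion_clinical: np.ndarray  # ml/100g/min
    eps3: np.ndarray
    eps2: np.ndarray

    @property
    def grid_shape(self) -> tuple:
        return self.brain_mask.shape

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_edge**3)

    def voxel_centers(self) -> np.ndarray:
        l = self.voxel_edge
        grids = np.meshgrid(
            *[(np.arange(n) + 0.5) * l for n in self.grid_shape], indexing="ij"
        )
        return np.stack(grids, axis=-1)


def load_tissue_maps(
    paths: dict,
    target_voxel_edge: float,
    resample_order: int = 0,
) -> TissueMap:
    """Load one NIfTI fraction volume per tissue class into a TissueMap.

    All volumes must share a common grid. The affine is used only for the
    source voxel size; volumes are resampled to an isotropic grid at
    ``target_voxel_edge`` (nearest-neighbor by default, which preserves
    fraction bounds; ``resample_order=1`` for trilinear). Per-voxel sums
    above 1 are renormalized down to 1.
    """
    missing = [c for c in TISSUE_CLASSES if c not in paths]
    if missing:
        raise KeyError(f"missing tissue classes: {missing}")
    vols = {}
    shape = None
    zooms = None
    for cls in TISSUE_CLASSES:
        img = nib.load(str(paths[cls]))
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim != 3:
            raise ShapeError(f"{cls}: expected a 3D volume, got {data.ndim}D")
        if shape is None:
            shape, zooms = data.shape, img.header.get_zooms()[:3]
        elif data.shape != shape:
            raise ShapeError(
                f"{cls}: grid {data.shape} does not match {shape}"
            )
        if np.any(data < -1e-9) or np.any(data > 1 + 1e-9):
            raise ValueError(f"{cls}: fractions outside [0, 1]")
        vols[cls] = np.clip(data, 0.0, 1.0)

    # NIfTI zooms are in mm
    src_edge = float(np.mean(zooms)) * 1e-3
    factor = src_edge / target_voxel_edge
    if not np.isclose(factor, 1.0):
        vols = {
            c: np.clip(
                ndimage.zoom(v, factor, order=resample_order, grid_mode=True,
                             mode="grid-constant"),
                0.0, 1.0)
            for c, v in vols.items()
        }
    frac = np.stack([vols[c] for c in TISSUE_CLASSES], axis=-1)
    total = frac.sum(axis=-1)
    over = total > 1.0
    if np.any(over):
        frac[over] /= total[over][..., None]
    return TissueMap(frac, target_voxel_edge)


def save_tissue_maps(tmap: TissueMap, out_dir, prefix: str = "tissue") -> dict:
    """Write one NIfTI volume per class; returns the path mapping."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    edge_mm = tmap.voxel_edge * 1e3
    affine = np.diag([edge_mm, edge_mm, edge_mm, 1.0])
    paths = {}
    for i, cls in enumerate(TISSUE_CLASSES):
        img = nib.Nifti1Image(tmap.fractions[..., i].astype(np.float32), affine)
        path = os.path.join(out_dir, f"{prefix}_{cls}.nii.gz")
        nib.save(img, path)
        paths[cls] = path
    return paths


def build_domain(tmap: TissueMap, params: PhysicalParams) -> PorousDomain:
    """Mix class properties into per-voxel fields and build the masks.

    Mixed properties are fraction-weighted means of the class values,
    normalized by the total tissue fraction so a voxel that is entirely
    one class takes exactly that class's value. Voxels whose total tissue
    fraction is below 0.5 are treated as air and excluded from the
    computational domain.
    """
    frac = tmap.fractions
    total = frac.sum(axis=-1)
    tissue_mask = total >= AIR_THRESHOLD
    if not np.any(tissue_mask):
        raise DomainError("no tissue voxels in the map")

    grey = tmap.class_fraction("grey")
    white = tmap.class_fraction("white")
    brain_mask = (grey + white >= BRAIN_THRESHOLD) & tissue_mask
    if not np.any(brain_mask):
        raise DomainError("empty brain mask")
    core_mask = (white > CORE_WHITE_THRESHOLD) & brain_mask

    safe_total = np.where(total > 0, total, 1.0)

    def mix(values: np.ndarray) -> np.ndarray:
        out = np.tensordot(frac, values, axes=([-1], [0])) / safe_total
        out[~tissue_mask] = 0.0
        return out

    rho = params.class_array("density")
    c = params.class_array("heat_capacity")
    rho_c = mix(rho * c)
    conductivity = mix(params.class_array("conductivity"))
    q_gen = mix(params.class_array("metabolic_rate"))
    w_clin = mix(params.class_array("perfusion"))
    density = mix(rho)
    eps3 = mix(params.class_array("blood_volume_fraction"))
    eps3[~brain_mask] = 0.0
    eps2 = 1.0 - eps3

    perfusion_vol = np.zeros_like(w_clin)
    perfusion_vol[tissue_mask] = perfusion_to_volumetric(
        w_clin[tissue_mask], density[tissue_mask], params.blood_density
    )

    surface_mask = _surface_shell(tissue_mask)
    return PorousDomain(
        voxel_edge=tmap.voxel_edge,
        brain_mask=brain_mask,
        core_mask=core_mask,
        tissue_mask=tissue_mask,
        surface_mask=surface_mask,
        rho_c=rho_c,
        conductivity=conductivity,
        q_gen=q_gen,
        perfusion_vol=perfusion_vol,
        perfusion_clinical=w_clin,
        eps3=eps3,
        eps2=eps2,
    )


def _surface_shell(tissue_mask: np.ndarray) -> np.ndarray:
    """Non-air voxels with at least one air face (grid edge counts as air)."""
    padded = np.pad(tissue_mask, 1, constant_values=False)
    has_air_face = np.zeros_like(tissue_mask)
    for ax in range(3):
        for shift in (-1, 1):
            neigh = np.roll(padded, shift, axis=ax)[1:-1, 1:-1, 1:-1]
            has_air_face |= ~neigh
    return tissue_mask & has_air_face


#: Neonatal scaling defaults: the head is geometrically scaled by 11/15,
#: perfusion rescaled to a brain average of 30 ml/100g/min, metabolism halved.
NEONATAL_SCALE = 11.0 / 15.0
NEONATAL_MEAN_PERFUSION = 30.0  # ml/100g/min
NEONATAL_METABOLISM_FACTOR = 0.5


def apply_neonatal_scaling(
    tmap: TissueMap,
    params: PhysicalParams,
    scale: float = NEONATAL_SCALE,
    mean_perfusion: float = NEONATAL_MEAN_PERFUSION,
    metabolism_factor: float = NEONATAL_METABOLISM_FACTOR,
) -> tuple:
    """Scale an adult head model down to a neonatal one.

    The voxel edge shrinks by ``scale``; all class perfusion values are
    rescaled by one common factor so that the brain-volume-weighted mean
    perfusion equals ``mean_perfusion`` (preserving the relative perfusion
    ratios between classes); metabolic heat generation is multiplied by
    ``metabolism_factor``. Other parameters are unchanged.
    """
    domain = build_domain(tmap, params)
    brain_perf = domain.perfusion_clinical[domain.brain_mask]
    mean_w = float(brain_perf.mean())
    if mean_w <= 0:
        raise ZeroDivisionError("brain perfusion is zero; cannot rescale")
    factor = mean_perfusion / mean_w
    new_params = params.with_updates(
        perfusion={c: w * factor for c, w in params.perfusion.items()},
        metabolic_rate={
            c: q * metabolism_factor for c, q in params.metabolic_rate.items()
        },
    )
    new_map = TissueMap(tmap.fractions.copy(), tmap.voxel_edge * scale)
    return new_map, new_params
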