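"""Physical parameters of the vascular-porous bioheat model.

All values are stored in SI units (temperatures in degrees Celsius).
Perfusion is carried in the clinical convention, ml of blood per 100 g
of tissue per minute, and converted to a volumetric mass rate
(kg blood / m^3 tissue / s) where the energy balance needs it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Tissue classes, in the fixed order used throughout the package.
TISSUE_CLASSES = ("grey", "white", "csf", "bone", "scalp")


def _cls(grey, white, csf, bone, scalp):
    return {"grey": grey, "white": white, "csf": csf, "bone": bone, "scalp": scalp}


@dataclass(frozen=True)
class PhysicalParams:
    """Per-class tissue properties, blood properties and model constants.

    Defaults are the standard adult parameter set for cerebral bioheat
    modelling: grey/white matter perfusion of 80/20 ml/100g/min, blood at
    1050 kg/m^3, a Nusselt number of 4 for laminar tube flow, and a
    Carman-Kozeny capillary bed with 10 um capillaries of tortuosity 1.6.
    """

    # per-tissue-class values
    density: dict = field(default_factory=lambda: _cls(1030.0, 1030.0, 1000.0, 1520.0, 1000.0))  # kg/m^3
    heat_capacity: dict = field(default_factory=lambda: _cls(3700.0, 3700.0, 3800.0, 1590.0, 4000.0))  # J/kg/degC
    conductivity: dict = field(default_factory=lambda: _cls(0.49, 0.49, 0.5, 1.16, 0.342))  # W/m/degC
    metabolic_rate: dict = field(default_factory=lambda: _cls(16700.0, 4175.0, 0.0, 368.3, 363.4))  # W/m^3
    perfusion: dict = field(default_factory=lambda: _cls(80.0, 20.0, 0.0, 1.8, 2.0))  # ml/100g/min
    blood_volume_fraction: dict = field(default_factory=lambda: _cls(0.0672, 0.0405, 0.0, 0.0, 0.0))  # --

    # blood
    blood_density: float = 1050.0  # kg/m^3
    blood_heat_capacity: float = 3800.0  # J/kg/degC
    blood_conductivity: float = 0.492  # W/m/degC
    blood_viscosity: float = 3.5e-3  # Pa s

    # model constants
    arterial_temperature: float = 37.0  # degC
    nusselt: float = 4.0  # --
    capillary_diameter: float = 10e-6  # m
    tortuosity: float = 1.6  # --
    flow_reversal: float = 1.0  # C_R, dimensionless

    def __post_init__(self):
        for name in ("density", "heat_capacity", "conductivity"):
            vals = getattr(self, name)
            if any(v <= 0 for v in vals.values()):
                raise ValueError(f"{name} values must be strictly positive")
        for name in ("metabolic_rate", "perfusion", "blood_volume_fraction"):
            vals = getattr(self, name)
            if any(v < 0 for v in vals.values()):
                raise ValueError(f"{name} values must be non-negative")
        for name in (
            "blood_density",
            "blood_heat_capacity",
            "blood_conductivity",
            "blood_viscosity",
            "nusselt",
            "capillary_diameter",
            "tortuosity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def class_array(self, name: str) -> np.ndarray:
        """Values of property `name` over TISSUE_CLASSES, as a vector."""
        vals = getattr(self, name)
        return np.array([vals[c] for c in TISSUE_CLASSES], dtype=float)

    def with_updates(self, **kwargs) -> "PhysicalParams":
        return replace(self, **kwargs)


def perfusion_to_volumetric(w_clinical, tissue_density, blood_density=1050.0):
    """Convert perfusion from ml/100g/min to kg blood / m^3 tissue / s.

    w [kg/m^3/s] = w [ml/100g/min] * 1e-6 m^3/ml * rho_tissue / 0.1 kg
                   / 60 s * rho_blood
    """
    w = np.asarray(w_clinical, dtype=float)
    rho = np.asarray(tissue_density, dtype=float)
    return w * 1e-6 * rho / 0.1 / 60.0 * blood_density
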