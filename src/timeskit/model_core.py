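"""Equilibrium binding chemistry, electrostatic surface partition, and
channel hydrodynamics shared by all pipeline stages.

Concentrations are SI (mol/m³) internally.  1 μM = 1e-3 mol/m³ and
1 nM = 1e-6 mol/m³; the :data:`MICROMOLAR` / :data:`NANOMOLAR` constants
convert at module boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import constants

# mol/m³ per unit of the named concentration
MOLAR = 1.0e3
MILLIMOLAR = 1.0
MICROMOLAR = 1.0e-3
NANOMOLAR = 1.0e-6

_CONCENTRATION_UNITS = {
    "M": MOLAR,
    "mM": MILLIMOLAR,
    "uM": MICROMOLAR,
    "µM": MICROMOLAR,
    "μM": MICROMOLAR,
    "nM": NANOMOLAR,
    "pM": 1.0e-9,
    "mol/m^3": 1.0,
    "mol/m3": 1.0,
}


def parse_concentration(value: float | str, unit: str | None = None) -> float:
    """Convert a concentration to mol/m³.

    Accepts either a plain number with a ``unit`` string, or a string like
    ``"100 uM"`` / ``"32.1nM"``.
    """
    if isinstance(value, str):
        s = value.strip()
        for suffix, scale in sorted(_CONCENTRATION_UNITS.items(), key=lambda kv: -len(kv[0])):
            if s.endswith(suffix):
                return float(s[: -len(suffix)].strip()) * scale
        return float(s)  # bare number: already mol/m³
    if unit is None:
        return float(value)
    try:
        return float(value) * _CONCENTRATION_UNITS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


@dataclass(frozen=True)
class SpeciesParams:
    """Physical parameters of one molecular species.

    Parameters
    ----------
    name
        Species label ("protein", "ligand", "complex", or a molecule name).
    diffusivity
        Bulk diffusion coefficient D, m²/s.
    effective_charge
        Net charge in multiples of the elementary charge (signed).
    partition_gamma
        Boltzmann surface partition factor γ (dimensionless); the ratio of
        the concentration just outside the Debye layer to the bulk value.
    kernel
        Per-molecule induced-charge template q(t) (``surface_signal.ChargeKernel``).
    """

    name: str
    diffusivity: float
    effective_charge: float = 0.0
    partition_gamma: float = 1.0
    kernel: Any = None

    def __post_init__(self) -> None:
        if not self.diffusivity > 0:
            raise ValueError(f"diffusivity must be > 0, got {self.diffusivity}")
        if not self.partition_gamma > 0:
            raise ValueError(f"partition_gamma must be > 0, got {self.partition_gamma}")


@dataclass(frozen=True)
class ChannelGeometry:
    """Microfluidic channel and electrode geometry plus buffer properties.

    ``half_height`` is L; the physical channel height is 2L (x = L is the
    channel centre-line, x = 0 the electrode surface).
    """

    half_height: float = 15e-6          # m; 30 μm tall channel
    width: float = 0.5e-3               # m
    electrode_area: float = 1e-6        # m²; 1 × 1 mm sensing pad
    buffer_viscosity: float = 1.0e-3    # Pa·s, water at room temperature
    temperature: float = 298.15         # K
    zeta_potential: float = -0.025      # V
    ionic_strength: float = 5.0         # mol/m³ (5 mM Tris-HCl)

    def __post_init__(self) -> None:
        for name in ("half_height", "width", "electrode_area",
                     "buffer_viscosity", "temperature", "ionic_strength"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def height(self) -> float:
        return 2.0 * self.half_height


@dataclass(frozen=True)
class BindingPair:
    """A protein–ligand pair, its complex, and the dissociation constant."""

    protein: SpeciesParams
    ligand: SpeciesParams
    complex: SpeciesParams
    kd: float  # mol/m³

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"kd must be > 0, got {self.kd}")


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium concentrations (mol/m³) of free protein, free ligand and
    complex for given initial concentrations."""

    n_protein: float
    n_ligand: float
    n_complex: float

    def __iter__(self):
        return iter((self.n_protein, self.n_ligand, self.n_complex))


def equilibrium_complex(x: float, y: float, kd: float) -> EquilibriumState:
    """Equilibrium speciation of P + L ⇌ C from initial concentrations.

    ``x`` and ``y`` are the pre-reaction protein and ligand concentrations;
    mass balance plus n_P·n_L = K_D·n_C gives the quadratic

        n_C² − (x + y + K_D)·n_C + x·y = 0,

    whose smaller root is the physical one (the larger root exceeds
    min(x, y)).  Computed in the Citardauq form 2xy / (b + √(b²−4xy)) to
    avoid cancellation when K_D ≪ x, y.

    All quantities in mol/m³ (any single consistent unit works: the
    relation is scale-invariant).
    """
    if x < 0 or y < 0:
        raise ValueError(f"initial concentrations must be >= 0, got x={x}, y={y}")
    if not kd > 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    if x == 0.0 or y == 0.0:
        return EquilibriumState(n_protein=x, n_ligand=y, n_complex=0.0)
    b = x + y + kd
    disc = b * b - 4.0 * x * y
    if disc < 0.0:
        if disc < -1e-12 * b * b:  # cannot happen analytically
            raise FloatingPointError(
                f"negative discriminant {disc} for x={x}, y={y}, kd={kd}")
        disc = 0.0
    n_c = 2.0 * x * y / (b + math.sqrt(disc))
    n_c = min(n_c, x, y)  # guard rounding at the K_D → 0 limit
    return EquilibriumState(n_protein=x - n_c, n_ligand=y - n_c, n_complex=n_c)


def boltzmann_partition(effective_charge: float, zeta: float,
                        temperature: float = 298.15) -> float:
    """Boltzmann surface partition factor γ = exp(−Ze·e·ζ / (k_B·T)).

    γ is the equilibrium ratio of the molecular concentration just outside
    the electrode's Debye layer to the bulk concentration, set by the work
    Ze·ζ of moving the charge through the interfacial potential.  For a
    fixed buffer and electrode it is a constant per species.
    """
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    u = effective_charge * constants.e * zeta / (constants.k * temperature)
    return math.exp(-u)


def wall_shear_stress(flow_rate: float, geometry: ChannelGeometry) -> float:
    """Wall shear stress (Pa) of pressure-driven laminar flow.

    For a parallel-plate channel of height h = 2L and width w,
    τ_w = 6·μ·Q / (w·h²) — linear in the volumetric flow rate Q (m³/s).
    """
    if flow_rate < 0:
        raise ValueError(f"flow_rate must be >= 0, got {flow_rate}")
    h = geometry.height
    return 6.0 * geometry.buffer_viscosity * flow_rate / (geometry.width * h * h)


def channel_width_from_shear(flow_rate: float, shear: float, height: float,
                             viscosity: float = 1.0e-3) -> float:
    """Invert the parallel-plate shear formula for the channel width.

    Calibrates w from one measured (flow rate, wall shear) pair,
    w = 6·μ·Q / (τ_w·h²), with h the full channel height.
    """
    if not (flow_rate > 0 and shear > 0 and height > 0 and viscosity > 0):
        raise ValueError("flow_rate, shear, height, viscosity must be > 0")
    return 6.0 * viscosity * flow_rate / (shear * height * height)


def debye_length(ionic_strength: float, temperature: float = 298.15,
                 relative_permittivity: float = 78.5) -> float:
    """Debye screening length (m) of a symmetric 1:1 electrolyte.

    λ_D = sqrt(ε₀·ε_r·k_B·T / (2·N_A·e²·I)) with the ionic strength I in
    mol/m³.  Order 1 nm for typical buffer ionic strengths.
    """
    if not ionic_strength > 0:
        raise ValueError(f"ionic_strength must be > 0, got {ionic_strength}")
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    eps = constants.epsilon_0 * relative_permittivity
    denom = 2.0 * constants.N_A * constants.e**2 * ionic_strength
    return math.sqrt(eps * constants.k * temperature / denom)


FLOW_UL_PER_MIN = 1e-9 / 60.0  # m³/s per μL/min


def flow_ul_min_to_si(q_ul_min: float) -> float:
    """Convert a flow rate in μL/min to m³/s."""
    return q_ul_min * FLOW_UL_PER_MIN
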