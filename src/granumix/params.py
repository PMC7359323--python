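"""Material, process, geometry and contact-model parameter containers.

The nine material/process descriptors below are the degrees of freedom of a
desk-scale agitated-filter-dryer mixing study: six particle properties
(radius, density, restitution, cohesive energy density, sliding friction,
Young's modulus) and three process settings (particle count, impeller speed,
cake height).  They double as the feature columns of the surrogate stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

#: Canonical descriptor order used by feature tables and the surrogate stage.
DESCRIPTOR_NAMES = (
    "particle_radius",
    "density",
    "restitution",
    "cohesion_energy_density",
    "friction",
    "youngs_modulus",
    "n_particles",
    "rpm",
    "cake_height",
)


@dataclass(frozen=True)
class MaterialProcessParams:
    """The 9 descriptors defining one simulation (SI units).

    particle_radius : m, density : kg/m^3, restitution in (0, 1],
    cohesion_energy_density : J/m^3 (SJKR stickiness, may be 0),
    friction : dimensionless Coulomb coefficient (may be 0),
    youngs_modulus : N/m^2, n_particles : count, rpm : rev/min,
    cake_height : m (target fill depth of the bed).
    """

    particle_radius: float
    density: float
    restitution: float = 0.6
    cohesion_energy_density: float = 0.0
    friction: float = 0.3
    youngs_modulus: float = 5e6
    n_particles: int = 1000
    rpm: float = 60.0
    cake_height: float = 0.05

    def __post_init__(self) -> None:
        for name in ("particle_radius", "density", "youngs_modulus", "cake_height"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.restitution <= 1.0):
            raise ValueError("restitution must lie in (0, 1]")
        if self.cohesion_energy_density < 0:
            raise ValueError("cohesion_energy_density must be >= 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.rpm < 0:
            raise ValueError("rpm must be >= 0")

    @property
    def particle_mass(self) -> float:
        """Sphere mass (4/3) pi R^3 rho in kg."""
        return (4.0 / 3.0) * math.pi * self.particle_radius**3 * self.density

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class VesselGeometry:
    """Flat-bottomed cylindrical vessel with flat vertical blades.

    Blades span the radius from the axis to the wall, extend from the floor
    up to ``blade_height``, and rotate about the vessel axis at the impeller
    speed.  This is a minimal agitated-filter-dryer abstraction.
    """

    vessel_radius: float
    blade_count: int = 2
    blade_height: float = 0.05
    blade_angle0: float = 0.0  # initial angular position, rad

    def __post_init__(self) -> None:
        if self.vessel_radius <= 0:
            raise ValueError("vessel_radius must be positive")
        if self.blade_count < 0:
            raise ValueError("blade_count must be >= 0")
        if self.blade_height <= 0:
            raise ValueError("blade_height must be positive")


def damping_ratio_from_restitution(e: float) -> float:
    """beta = ln e / sqrt(ln^2 e + pi^2); 0 for e = 1 (no dissipation)."""
    if not (0.0 < e <= 1.0):
        raise ValueError("restitution must lie in (0, 1]")
    if e == 1.0:
        return 0.0
    ln_e = math.log(e)
    return ln_e / math.sqrt(ln_e * ln_e + math.pi * math.pi)


def rayleigh_time(radius: float, density: float, youngs_modulus: float,
                  poisson_ratio: float = 0.3) -> float:
    """Rayleigh surface-wave time of a sphere, the DEM stability scale.

    t_R = pi R sqrt(rho / G) / (0.1631 nu + 0.8766) with shear modulus
    G = E / (2 (1 + nu)).
    """
    shear = youngs_modulus / (2.0 * (1.0 + poisson_ratio))
    return (math.pi * radius * math.sqrt(density / shear)
            / (0.1631 * poisson_ratio + 0.8766))


@dataclass(frozen=True)
class ContactModelParams:
    """Derived/numerical parameters of the Hertz-Mindlin + SJKR contact model.

    ``timestep_dt`` defaults to ``dt_safety`` times the Rayleigh critical
    time, the standard DEM stability margin.  ``gravity`` points along -z.
    """

    poisson_ratio: float = 0.3
    dt_safety: float = 0.2
    timestep_dt: float | None = None
    gravity: float = 9.81
    tangential_stiffness_ratio: float = 1.0  # multiplier on the Mindlin k_t

    def __post_init__(self) -> None:
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if not (0.0 < self.dt_safety <= 1.0):
            raise ValueError("dt_safety must lie in (0, 1]")
        if self.timestep_dt is not None and self.timestep_dt <= 0:
            raise ValueError("timestep_dt must be positive")
        if self.gravity < 0:
            raise ValueError("gravity magnitude must be >= 0")

    def resolve_dt(self, params: MaterialProcessParams) -> float:
        """Explicit dt if set, else dt_safety x Rayleigh time."""
        if self.timestep_dt is not None:
            return self.timestep_dt
        return self.dt_safety * rayleigh_time(
            params.particle_radius, params.density,
            params.youngs_modulus, self.poisson_ratio)

    def effective_youngs(self, params: MaterialProcessParams) -> float:
        """Sphere-sphere effective modulus E* = E / (2 (1 - nu^2))."""
        return params.youngs_modulus / (2.0 * (1.0 - self.poisson_ratio**2))

    def effective_shear(self, params: MaterialProcessParams) -> float:
        """Sphere-sphere effective shear modulus G* for the Mindlin spring.

        1/G* = 2 (2 - nu)(1 + nu)/E per sphere -> G* = E / (4 (2 - nu)(1 + nu)).
        """
        nu = self.poisson_ratio
        g = params.youngs_modulus / (4.0 * (2.0 - nu) * (1.0 + nu))
        return g * self.tangential_stiffness_ratio
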