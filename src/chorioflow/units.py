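"""Physical properties and lattice/physical unit mapping.

The solver works in lattice units (cell = 1, step = 1, reference density = 1).
:func:`map_units` fixes the time step by diffusive scaling — the lattice
kinematic viscosity ``cs2 * (tau - 1/2)`` must equal ``nu_phys * dt / dx**2``
— and derives the conversion factors for velocity, pressure and stress.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class FluidProperties:
    """Bulk properties of blood modelled as a Newtonian fluid.

    Defaults are whole-blood values: density 1060 kg/m^3 and kinematic
    viscosity 3.8e-6 m^2/s.
    """

    density: float = 1060.0            # kg/m^3
    kinematic_viscosity: float = 3.8e-6  # m^2/s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.kinematic_viscosity <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def dynamic_viscosity(self) -> float:
        """mu = rho * nu, in Pa s."""
        return self.density * self.kinematic_viscosity


@dataclass(frozen=True)
class UnitSystem:
    """Conversion factors between lattice and physical (SI) units."""

    dx: float    # m per cell
    dt: float    # s per step
    tau: float   # relaxation time, lattice units
    cs2: float   # squared lattice sound speed
    rho_phys: float  # kg/m^3 mapped to lattice density 1

    def __post_init__(self) -> None:
        if self.tau <= 0.5:
            raise ValueError("tau must exceed 1/2 for positive viscosity")

    @property
    def nu_lattice(self) -> float:
        return self.cs2 * (self.tau - 0.5)

    @property
    def velocity_scale(self) -> float:
        """m/s per lattice velocity unit."""
        return self.dx / self.dt

    @property
    def pressure_scale(self) -> float:
        """Pa per lattice pressure (or stress) unit."""
        return self.rho_phys * self.velocity_scale**2

    @property
    def strain_rate_scale(self) -> float:
        """1/s per lattice strain-rate unit."""
        return 1.0 / self.dt

    def pressure_to_lattice(self, delta_p_pa: float) -> float:
        """Convert a physical pressure difference to lattice units."""
        return delta_p_pa / self.pressure_scale

    def acceleration_to_lattice(self, a_phys: float) -> float:
        """Convert m/s^2 to lattice acceleration (cells/step^2)."""
        return a_phys * self.dt**2 / self.dx


def map_units(fluid: FluidProperties, dx: float, tau: float = 0.8,
              cs2: float = 1.0 / 3.0, max_mach_velocity: float | None = None,
              ) -> UnitSystem:
    """Fix the lattice time step by matching kinematic viscosity.

    Parameters
    ----------
    fluid : FluidProperties
    dx : float
        Cell edge in metres.
    tau : float
        BGK relaxation time (> 0.5); larger tau means a larger stable time
        step at the cost of accuracy near walls.
    max_mach_velocity : float, optional
        Expected peak physical velocity (m/s); if the implied lattice
        velocity exceeds 0.1 * c_s a warning advises a finer dx / larger tau.
    """
    if tau <= 0.5:
        raise ValueError("tau must exceed 1/2")
    if dx <= 0:
        raise ValueError("dx must be positive")
    dt = cs2 * (tau - 0.5) * dx**2 / fluid.kinematic_viscosity
    units = UnitSystem(dx=dx, dt=dt, tau=tau, cs2=cs2, rho_phys=fluid.density)
    if max_mach_velocity is not None:
        u_lat = max_mach_velocity / units.velocity_scale
        if u_lat > 0.1 * cs2**0.5:
            warnings.warn(
                "expected velocity implies lattice Mach > 0.1; "
                "use a larger tau or finer dx", stacklevel=2)
    return units
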