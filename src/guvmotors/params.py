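"""Parameter containers for the micromotor-in-GUV simulation.

All lengths are micrometres, times seconds, fuel concentrations % v/v
hydrogen peroxide. The particle is an enzymatically propelled coacervate
droplet (~1.2 um diameter); the compartment is a giant unilamellar
vesicle (GUV, 10-50 um diameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant, J/K
KB = 1.380649e-23

#: Default coacervate particle diameter, um
PARTICLE_DIAMETER_UM = 1.2

#: Membrane permeability of a plain lipid bilayer to H2O2, m/s
BILAYER_PERMEABILITY_M_S = 1.1e-6


@dataclass
class MotorParams:
    """Intrinsic motility parameters of a single coacervate motor.

    ``D_T0`` is the passive translational diffusion coefficient (um^2/s),
    ``D_R`` the rotational diffusion coefficient (1/s); the rotational
    relaxation time ``tau_R`` is 1/D_R by convention. Propulsion speed
    saturates with fuel as v = v_max * c / (K_fuel + c).
    """

    D_T0: float = 0.2        # um^2/s
    D_R: float = 2.0         # 1/s; effective decorrelation of the propulsion axis
    v_max: float = 0.79      # um/s, saturating propulsion speed
    K_fuel: float = 0.1      # % v/v (~30 mM H2O2), catalase half-saturation
    radius_p: float = PARTICLE_DIAMETER_UM / 2.0  # um

    def __post_init__(self) -> None:
        for name in ("D_T0", "D_R", "v_max", "K_fuel", "radius_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MotorParams.{name} must be strictly positive")

    @property
    def tau_R(self) -> float:
        """Rotational relaxation time, s (= 1/D_R)."""
        return 1.0 / self.D_R


@dataclass
class CompartmentParams:
    """Spherical GUV compartment and its hydrodynamic wall coupling.

    The mobility factor m(d) = m_min + (1 - m_min) * d / (d + lambda_wall),
    with d the gap between particle surface and membrane, encodes the
    1/L growth of viscous drag near a no-slip boundary. ``lambda_wall``
    is the gap at which mobility is halfway between m_min and 1;
    ``m_min`` is the mobility floor at contact. The default
    ``lambda_wall`` exceeds the GUV radius, so inside the compartment the
    mobility is nearly proportional to the distance to the boundary —
    drag scales like 1/L throughout the interior, not just in a thin
    wall layer. ``permeability`` (m/s) governs fuel exchange across the
    membrane.
    """

    R_guv: float = 12.0            # um
    lambda_wall: float = 45.0      # um; 0 disables wall coupling
    m_min: float = 0.02            # unitless, (0, 1]
    permeability: float = BILAYER_PERMEABILITY_M_S  # m/s
    fuel_outside: float = 0.0      # % v/v

    def __post_init__(self) -> None:
        if not self.R_guv > 0:
            raise ValueError("R_guv must be positive")
        if self.lambda_wall < 0:
            raise ValueError("lambda_wall must be non-negative")
        if not 0 < self.m_min <= 1:
            raise ValueError("m_min must be in (0, 1]")
        if self.permeability < 0:
            raise ValueError("permeability must be non-negative")


#: Stand-in compartment for bulk (unconfined) runs: radius far larger
#: than any displacement reachable in 60 s, wall coupling off.
def bulk_compartment() -> CompartmentParams:
    return CompartmentParams(R_guv=1e6, lambda_wall=0.0, m_min=1.0)


@dataclass
class AcquisitionParams:
    """Video acquisition parameters: 5 frames/s for 60 s by default,
    integrated at a finer Euler-Maruyama step.

    ``localization_sd`` is the static localization error of the tracked
    centroid (um per axis, iid Gaussian on each recorded position). It
    adds a constant 4*sigma^2 offset to measured 2D MSDs, which at low
    true MSD depresses the apparent anomalous exponent — a well-known
    feature of single-particle tracking data that the synthetic videos
    must share. Set 0 for noise-free ground truth.
    """

    frame_rate: float = 5.0       # 1/s
    duration: float = 60.0        # s
    dt_integration: float = 0.01  # s
    localization_sd: float = 0.08  # um
    seed: int = 0

    def __post_init__(self) -> None:
        frame_dt = 1.0 / self.frame_rate
        if self.localization_sd < 0:
            raise ValueError("localization_sd must be non-negative")
        if self.dt_integration > frame_dt + 1e-12:
            raise ValueError("dt_integration must not exceed the frame interval")
        n_sub = frame_dt / self.dt_integration
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("frame interval must be an integer multiple of dt_integration")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def n_substeps(self) -> int:
        return int(round(self.frame_interval / self.dt_integration))

    @property
    def n_frames(self) -> int:
        """Recorded frames, inclusive of t = 0."""
        return int(round(self.duration * self.frame_rate)) + 1


@dataclass
class ParticleState:
    """Position (um, relative to compartment centre) and unit propulsion
    axis of one particle."""

    position: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.position.shape != (3,) or self.orientation.shape != (3,):
            raise ValueError("position and orientation must be 3-vectors")
        norm = float(np.linalg.norm(self.orientation))
        if norm == 0:
            raise ValueError("orientation must be non-zero")
        self.orientation = self.orientation / norm


@dataclass
class Trajectory:
    """Time-ordered XY positions (um) of one tracked particle at a
    uniform frame interval; the unit of all downstream MSD analysis."""

    particle_id: int
    times: np.ndarray   # s, strictly increasing, uniform
    xy: np.ndarray      # (n, 2) um

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if self.xy.shape != (len(self.times), 2):
            raise ValueError("xy must be (n_frames, 2)")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("frame interval must be uniform")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ExperimentCondition:
    """One experimental condition: fuel level, compartment geometry,
    particle count, membrane type and seed."""

    label: str
    fuel: float = 0.0                 # % v/v, in {0, 0.034, 0.85, 3.4} by default
    guv_diameter: float | str = "bulk"  # um, or "bulk" for unconfined
    n_particles: int = 40
    crowding_beta: float = 0.0        # um^3; 0 disables crowding
    membrane: str = "bilayer"         # "bilayer" | "alpha_hemolysin"
    seed: int = 0
    motor: MotorParams = field(default_factory=MotorParams)

    def __post_init__(self) -> None:
        if self.fuel < 0:
            raise ValueError("fuel concentration must be non-negative")
        if self.membrane not in ("bilayer", "alpha_hemolysin"):
            raise ValueError("membrane must be 'bilayer' or 'alpha_hemolysin'")
        if self.guv_diameter != "bulk":
            if float(self.guv_diameter) <= 2 * self.motor.radius_p:
                raise ValueError("GUV diameter must exceed the particle diameter")

    @property
    def is_bulk(self) -> bool:
        return self.guv_diameter == "bulk"


def stokes_einstein_DT(radius_p_um: float, viscosity_pa_s: float = 0.89e-3,
                       temperature_k: float = 298.15) -> float:
    """Translational Stokes-Einstein diffusion coefficient, um^2/s."""
    r = radius_p_um * 1e-6
    d = KB * temperature_k / (6 * math.pi * viscosity_pa_s * r)  # m^2/s
    return d * 1e12
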