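"""Brownian dynamics of self-propelled particles in spherical GUV confinement.

The model is an active Brownian particle (ABP): overdamped translation with
thermal noise ``D_T0``, propulsion at speed ``v`` along a body axis that
undergoes rotational diffusion ``D_R``, and a position-dependent scalar
mobility ``m(d)`` that encodes the increase of viscous drag near the no-slip
membrane (drag ~ 1/L with L the gap to the boundary). The mobility scales
the thermal mobility and its noise amplitude together (locally
fluctuation-dissipation consistent); the phoretic propulsion speed is not
attenuated, because confinement also steepens the product gradient that
drives the slip flow, offsetting the drag on self-propulsion. The membrane
is a hard wall at ``R_guv - radius_p`` handled by reflection. Recorded
positions carry the tracker's static localization error.

Propulsion speed follows a saturating (Michaelis-Menten) function of the
hydrogen peroxide fuel concentration, consistent with catalase kinetics;
fuel enters the vesicle across the membrane by passive permeation.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    AcquisitionParams,
    CompartmentParams,
    ExperimentCondition,
    KB,
    MotorParams,
    ParticleState,
    Trajectory,
    bulk_compartment,
)

__all__ = [
    "fuel_to_speed",
    "wall_mobility",
    "permeate_fuel",
    "crowding_factor",
    "rotational_time",
    "step",
    "simulate_trajectory",
    "simulate_condition",
    "simulate_ensemble_3d",
]


def fuel_to_speed(fuel: float, params: MotorParams) -> float:
    """Propulsion speed (um/s) at H2O2 concentration ``fuel`` (% v/v).

    Saturating law v = v_max * c / (K_fuel + c): zero without fuel,
    half-maximal at the half-saturation concentration ``K_fuel``.
    """
    if fuel < 0:
        raise ValueError("fuel concentration must be non-negative")
    if fuel == 0:
        return 0.0
    return params.v_max * fuel / (params.K_fuel + fuel)


def wall_mobility(position: np.ndarray, comp: CompartmentParams,
                  radius_p: float = 0.6) -> float:
    """Scalar mobility factor m in [m_min, 1] at ``position`` (um).

    m(d) = m_min + (1 - m_min) * d / (d + lambda_wall) with
    d = R_guv - |position| - radius_p the surface-to-membrane gap, so the
    effective drag grows like 1/d approaching the wall and m -> 1 in bulk.
    """
    position = np.asarray(position, dtype=float)
    r = float(np.linalg.norm(position))
    if r > comp.R_guv + 1e-9:
        raise ValueError("position lies outside the compartment")
    if comp.lambda_wall == 0.0:
        return 1.0
    d = max(comp.R_guv - r - radius_p, 0.0)
    return comp.m_min + (1.0 - comp.m_min) * d / (d + comp.lambda_wall)


def permeate_fuel(c_in: float, c_out: float, comp: CompartmentParams,
                  t: float) -> float:
    """Interior fuel concentration after time ``t`` (s) of passive permeation.

    Well-mixed sphere flux balance dc_in/dt = (3P/R)(c_out - c_in), hence
    exponential relaxation toward c_out with time constant R/(3P).
    """
    if c_in < 0 or c_out < 0:
        raise ValueError("concentrations must be non-negative")
    if t < 0:
        raise ValueError("time must be non-negative")
    p_um_s = comp.permeability * 1e6  # m/s -> um/s
    if p_um_s == 0.0:
        return c_in
    rate = 3.0 * p_um_s / comp.R_guv  # 1/s
    return c_out + (c_in - c_out) * math.exp(-rate * t)


def crowding_factor(n_particles: int, R_guv: float, beta: float) -> float:
    """Mean-field speed attenuation f in (0, 1] from particle crowding.

    f = 1 / (1 + beta * rho) with rho = n / ((4/3) pi R^3) the number
    density (1/um^3); neighbouring motors flatten each other's product
    gradient and deplete fuel locally, so propulsion weakens with density.
    ``beta`` (um^3) sets the strength; beta = 0 disables the effect.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    rho = n_particles / ((4.0 / 3.0) * math.pi * R_guv**3)
    return 1.0 / (1.0 + beta * rho)


def rotational_time(radius_p: float, viscosity: float = 0.89e-3,
                    temperature: float = 298.15) -> float:
    """Stokes-Einstein-Debye rotational relaxation time tau_R (s).

    D_R = k_B T / (8 pi mu r^3); tau_R = 1/D_R. For a 1.2 um sphere in
    water at 25 degC this gives ~1.3 s, of the order of the 1.5-3 s
    decorrelation window the acquisition rate is designed to resolve.
    """
    if radius_p <= 0 or viscosity <= 0 or temperature <= 0:
        raise ValueError("all arguments must be positive")
    r = radius_p * 1e-6  # m
    d_r = KB * temperature / (8.0 * math.pi * viscosity * r**3)  # 1/s
    return 1.0 / d_r


# ---------------------------------------------------------------------------
# Integration core.
#
# The ensemble integrator is vectorised over particles; per-particle noise
# streams are drawn from independent generators seeded as (master, index),
# so single-particle and ensemble runs agree bit-for-bit.
# ---------------------------------------------------------------------------


def _ensemble_step(pos: np.ndarray, ori: np.ndarray, xi: np.ndarray,
                   eta: np.ndarray, v: float, motor: MotorParams,
                   comp: CompartmentParams, dt: float) -> None:
    """One Euler-Maruyama step, in place, for (n, 3) position/orientation
    arrays with pre-drawn standard-normal noise ``xi`` (translation) and
    ``eta`` (rotation)."""
    r_eff = comp.R_guv - motor.radius_p
    if comp.lambda_wall > 0.0:
        r = np.linalg.norm(pos, axis=1)
        d = np.maximum(r_eff - r, 0.0)
        m = comp.m_min + (1.0 - comp.m_min) * d / (d + comp.lambda_wall)
        m = m[:, None]
    else:
        m = 1.0
    # mobility scales the thermal term (fluctuation-dissipation); the
    # phoretic propulsion is left unscaled: the boundary also steepens
    # the self-generated product gradient, compensating the extra drag
    # on the slip velocity
    drift = (v * dt) * ori if v != 0.0 else 0.0
    noise = np.sqrt(2.0 * motor.D_T0 * dt * m) * xi
    pos += drift + noise
    # hard wall: fold radial overshoot back inside (specular for small steps)
    r = np.linalg.norm(pos, axis=1)
    over = r > r_eff
    if np.any(over):
        scale = np.clip(2.0 * r_eff - r[over], 0.0, r_eff) / r[over]
        pos[over] *= scale[:, None]
    if motor.D_R > 0.0:
        dphi = np.sqrt(2.0 * motor.D_R * dt) * eta
        ori += np.cross(dphi, ori)
        ori /= np.linalg.norm(ori, axis=1)[:, None]


def step(state: ParticleState, motor: MotorParams, comp: CompartmentParams,
         dt: float, rng: np.random.Generator, v: float | None = None) -> ParticleState:
    """Advance one particle by one integration step of length ``dt`` (s).

    Propulsion drift v*e*dt plus thermal noise sqrt(2 m(d) D_T0 dt),
    reflecting boundary, rotational diffusion of the propulsion axis.
    ``v`` defaults to the fuel-free speed 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.all(np.isfinite(state.position)) and np.all(np.isfinite(state.orientation))):
        raise ValueError("particle state contains non-finite values")
    pos = state.position[None, :].copy()
    ori = state.orientation[None, :].copy()
    xi = rng.standard_normal((1, 3))
    eta = rng.standard_normal((1, 3))
    _ensemble_step(pos, ori, xi, eta, 0.0 if v is None else v, motor, comp, dt)
    return ParticleState(position=pos[0], orientation=ori[0])


def _init_positions(n: int, comp: CompartmentParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniform positions in the central sphere of radius R_guv/4 — motors
    are tracked starting far from the membrane, near the GUV centre."""
    r_init = min(comp.R_guv / 4.0, 25.0)  # bulk stand-in: start near origin
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    radii = r_init * rng.random(n) ** (1.0 / 3.0)
    return u * radii[:, None]


def _random_orientations(n: int, rng: np.random.Generator) -> np.ndarray:
    e = rng.standard_normal((n, 3))
    return e / np.linalg.norm(e, axis=1)[:, None]


def simulate_ensemble_3d(n_particles: int, motor: MotorParams,
                         comp: CompartmentParams, acq: AcquisitionParams,
                         v: float = 0.0, master_seed: int | None = None,
                         ) -> np.ndarray:
    """Simulate ``n_particles`` independent motors; return recorded 3D
    positions, shape (n_particles, n_frames, 3), in um.

    Integrates at ``acq.dt_integration`` and records every frame interval
    (frame 0 is the initial state). Noise for particle i comes from
    ``np.random.default_rng((master_seed, i))`` so ensembles are
    reproducible and particles independent.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    seed = acq.seed if master_seed is None else master_seed
    dt = acq.dt_integration
    n_frames = acq.n_frames
    n_sub = acq.n_substeps
    n_steps = (n_frames - 1) * n_sub

    rngs = [np.random.default_rng((seed, i)) for i in range(n_particles)]
    pos = np.stack([_init_positions(1, comp, r)[0] for r in rngs])
    ori = np.stack([_random_orientations(1, r)[0] for r in rngs])
    need_rot = motor.D_R > 0.0
    xi = np.stack([r.standard_normal((n_steps, 3)) for r in rngs])
    eta = (np.stack([r.standard_normal((n_steps, 3)) for r in rngs])
           if need_rot else np.zeros((n_particles, 1, 3)))

    out = np.empty((n_particles, n_frames, 3))
    out[:, 0] = pos
    k = 0
    for f in range(1, n_frames):
        for _ in range(n_sub):
            _ensemble_step(pos, ori, xi[:, k], eta[:, k] if need_rot else eta[:, 0],
                           v, motor, comp, dt)
            k += 1
        out[:, f] = pos
    if acq.localization_sd > 0:
        # static centroid error of the tracker; the reported position
        # cannot leave the compartment, so radial overshoot is clipped
        out += np.stack([r.normal(0.0, acq.localization_sd, (n_frames, 3))
                         for r in rngs])
        radii = np.linalg.norm(out, axis=2)
        over = radii > comp.R_guv
        if np.any(over):
            out[over] *= (comp.R_guv / radii[over])[:, None]
    return out


def _to_trajectories(pos3d: np.ndarray, acq: AcquisitionParams,
                     first_id: int = 0) -> list[Trajectory]:
    times = np.arange(pos3d.shape[1]) * acq.frame_interval
    return [Trajectory(particle_id=first_id + i, times=times, xy=pos3d[i, :, :2].copy())
            for i in range(pos3d.shape[0])]


def simulate_trajectory(motor: MotorParams, comp: CompartmentParams,
                        acq: AcquisitionParams, v: float = 0.0,
                        master_seed: int | None = None) -> Trajectory:
    """Simulate one motor and return its XY-projected trajectory sampled at
    the acquisition frame rate (as in the recorded videos: XY only, with
    the focal plane tracking the particle)."""
    pos = simulate_ensemble_3d(1, motor, comp, acq, v=v, master_seed=master_seed)
    return _to_trajectories(pos, acq)[0]


def simulate_condition(cond: ExperimentCondition, n_particles: int | None = None,
                       acq: AcquisitionParams | None = None,
                       return_3d: bool = False):
    """Simulate all particles of one experimental condition.

    The propulsion speed is the fuel-map speed at the condition's fuel
    level, attenuated by the mean-field crowding factor when
    ``crowding_beta`` > 0 (confined conditions only). Bulk conditions use
    an effectively unbounded compartment with wall coupling off.

    Returns a list of :class:`Trajectory`; with ``return_3d`` also the
    (n, frames, 3) position array.
    """
    n = cond.n_particles if n_particles is None else n_particles
    if n < 1:
        raise ValueError("n_particles must be >= 1")
    acq = acq or AcquisitionParams(seed=cond.seed)
    if cond.is_bulk:
        comp = bulk_compartment()
    else:
        comp = CompartmentParams(R_guv=float(cond.guv_diameter) / 2.0)
        if cond.membrane == "alpha_hemolysin":
            comp.permeability *= 100.0
    v = fuel_to_speed(cond.fuel, cond.motor)
    if cond.crowding_beta > 0 and not cond.is_bulk:
        v *= crowding_factor(n, comp.R_guv, cond.crowding_beta)
    pos = simulate_ensemble_3d(n, cond.motor, comp, acq, v=v,
                               master_seed=cond.seed)
    trajs = _to_trajectories(pos, acq)
    return (trajs, pos) if return_3d else trajs


def simulate_confined_mixture(fuel: float, seed: int, n_particles: int = 40,
                              diameter_range: tuple[float, float] = (14.0, 34.0),
                              motor: MotorParams | None = None,
                              acq: AcquisitionParams | None = None) -> list[Trajectory]:
    """Ensemble of motors across GUVs with diameters drawn uniformly from
    ``diameter_range`` (one particle per GUV), the standard confined study
    population. Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    trajs: list[Trajectory] = []
    for i in range(n_particles):
        dia = float(rng.uniform(*diameter_range))
        cond = ExperimentCondition(
            label=f"mix_{i}", fuel=fuel, guv_diameter=dia, n_particles=1,
            seed=int(rng.integers(2**31)), motor=motor or MotorParams())
        t = simulate_condition(cond, acq=acq)[0]
        t.particle_id = i
        trajs.append(t)
    return trajs
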