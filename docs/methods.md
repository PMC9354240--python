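# Methods

## The physical model

Each coacervate motor is an active Brownian particle (ABP) in three
dimensions inside a spherical compartment of radius `R_guv` (the GUV),
integrated with the Euler–Maruyama scheme:

    x(t+dt) = x(t) + v e dt + sqrt(2 m(d) D_T0 dt) ξ,   ξ ~ N(0, I₃)

- `D_T0` (µm²/s) is the passive translational diffusion coefficient in
  bulk. Default 0.2 µm²/s, the mid-range of what free ~1.2 µm coacervates
  show (Stokes–Einstein for a 1.2 µm sphere in water at 25 °C gives
  0.41 µm²/s; coacervates diffuse somewhat slower than hard spheres of
  equal size).
- `v` (µm/s) is the self-propulsion speed along the body axis `e`, set by
  the fuel map below; it is zero without fuel.
- `m(d) ∈ [m_min, 1]` is a scalar hydrodynamic mobility depending on the
  gap `d = R_guv − |x| − r_p` between particle surface and membrane
  (below).
- The membrane is a reflecting hard wall at `|x| = R_guv − r_p`: radial
  overshoot is folded back (`r → 2(R_guv−r_p) − r`), the specular limit
  for the ≤0.1 µm steps taken here. No adhesion — electrostatic
  attraction between coacervate and membrane is not expected for this
  chemistry.
- The axis `e` performs isotropic rotational diffusion: per step,
  `e → normalize(e + δφ × e)` with `δφ ~ N(0, 2 D_R dt I₃)`, which gives
  `⟨e(t)·e(0)⟩ = exp(−2 D_R t)` (verified against this closed form in the
  tests).

Integration uses `dt = 0.01 s`, stable for D ≤ 1 µm²/s and v ≤ 2 µm/s;
positions are recorded every 0.2 s (5 frames/s) for 60 s, 301 frames per
trajectory, matching the video acquisition. Analysis uses the XY
projection only, as in the recorded videos.

### Wall drag

Near a no-slip boundary, viscous drag on a phoretic particle grows
inversely with the distance L to the wall (σ = μ·u_s/L). We encode this as
a scalar mobility

    m(d) = m_min + (1 − m_min) · d / (d + λ_wall)

applied to the thermal term and its noise amplitude together (locally
fluctuation–dissipation consistent). Two regimes of the single functional
form: λ_wall small confines the drag to a thin wall layer; λ_wall larger
than the compartment makes mobility nearly proportional to the distance to
the boundary across the whole interior — drag ~ 1/L with L of the order of
the GUV radius, which is the relevant regime when motors roam a 7–17 µm
radius compartment. Defaults (one calibration pass against the confined
passive exponent, then frozen): `λ_wall = 45 µm`, `m_min = 0.02`. These
yield a confined passive short-lag D_T ≈ 0.04 µm²/s across the 14–34 µm
GUV population.

The propulsion drift is deliberately **not** multiplied by `m(d)`. The
same boundary that increases drag also steepens the self-generated product
gradient around the motor (a phoretic enhancement opposing the
hydrodynamic hindrance), and treating the slip speed as unattenuated is
the simplest phenomenology consistent with the observation that fuel
restores normal diffusion and doubles D_T even in confinement — a scaled
propulsion would require implausible speeds (~3 µm/s) to achieve the
measured enhancement through an m² suppression.

### Fuel map and rotational decorrelation

Propulsion speed follows saturating (Michaelis–Menten) kinetics,

    v(c) = v_max · c / (K_fuel + c),

with `K_fuel = 0.1% v/v` (≈30 mM H₂O₂, the order of catalase's Michaelis
constant — the enzyme is close to saturation at the working fuel levels)
and `v_max = 0.79 µm/s` calibrated once so that v(0.85%) doubles the
fitted confined D_T relative to zero fuel, then frozen.

`D_R = 2.0 s⁻¹` (τ_R = 0.5 s) is the *effective* decorrelation rate of the
propulsion axis. It is faster than the rigid-body rotational diffusion of
a 1.2 µm sphere (Stokes–Einstein–Debye gives ≈1.2 s, which
`rotational_time()` computes, and ~1.5–3 s for the upper end of the size
distribution): propulsion here arises from transiently clustering enzyme
patches on the droplet surface, so the propulsion direction decorrelates
with patch turnover, not only with body rotation. Slower decorrelation
(τ_R ≥ 1.2 s) produces a pronounced superdiffusive knee in the 0.2–10 s
fitting window that the measured MSD curves do not show.

### Membrane permeation and crowding

Fuel enters the vesicle through the membrane as a well-mixed sphere flux
balance, `dc_in/dt = (3P/R)(c_out − c_in)`, solved in closed form. With
the bilayer permeability P = 1.1×10⁻⁶ m/s the interior equilibrates with
time constant R/(3P) ≈ 3–5 s, i.e. within the first frames of a video;
α-hemolysin-porated membranes (P ×100) equilibrate within one frame.
Simulated conditions therefore apply the fuel map to the nominal fuel
level directly; the permeation operation is used for the membrane-control
analysis (`analysis/01`).

Crowding is mean-field: with n motors in a compartment, the speed is
scaled by `f = 1/(1 + β·ρ)`, ρ = n/((4/3)πR³). Neighbouring motors flatten
each other's product gradients and consume fuel locally; β (µm³, default 0
= off; 1500 in the crowding analysis, chosen once so that the high- vs
low-concentration MSD(10 s) contrast is of the observed order) sets the
strength. Passive motion is unaffected — matching the observation that
concentration groups are indistinguishable without fuel.

### Acquisition model: localization error

Recorded positions carry iid Gaussian localization error
`σ_loc = 0.08 µm` per axis (0.4 px at 0.2 µm/px; typical centroid
precision for bright-field tracking of ~1 µm particles), clipped so a
reported position never lies outside the compartment. Static localization
error adds a constant `4σ_loc²` to every measured 2D MSD value. This term
matters: a time-averaged MSD of Brownian motion with any smoothly
position-dependent mobility is *linear in lag* — drag rescales D_T but
cannot bend the curve, and geometric cage saturation is negligible when
60 s of slow diffusion explores ~2 µm of a ≥7 µm-radius compartment. What
makes the measured confined MSD visibly sub-linear on 0.2–10 s lags is the
noise offset relative to the drag-suppressed true MSD: with
D_T ≈ 0.04 µm²/s the offset is ~20% of the first-lag MSD and the log-log
slope drops to ≈0.85–0.90, while bulk motors (D_T ≈ 0.2) stay at ≈0.97.
The same term makes the apparent exponent rise toward 1 as fuel raises the
true MSD — the observed crossover — and makes α increase with GUV size.

## MSD analysis

- **Estimator**: time-averaged MSD per trajectory over all overlapping
  pairs (`tamsd`), then unweighted ensemble mean across particles with
  SEM = SD/√n (`ensemble_msd`). Verified exactly against an O(N²)
  brute-force double loop.
- **Anomalous exponent**: ordinary least squares of log MSD on log lag
  over 0.2–10 s (`fit_power_law`); α is the slope, K = exp(intercept).
  Log-log OLS keeps residuals scale-free across the lag decades. The
  window is configuration-exposed.
- **Diffusion coefficient**: least squares through the origin of
  MSD = 4·D_T·Δt over 0.2–3 s (`fit_linear`) — the first 3 s, where
  confinement has not yet bent the curve.
- **Regime labels**: |α−1| ≤ 0.05 is "normal" (so α = 1.01 classifies as
  normal diffusion), below sub-, above superdiffusive.
- **Group comparisons**: Welch's unequal-variance two-tailed t-test by
  default (Student's available by flag), with the usual
  0.05/0.01/0.001 asterisk tiers. Identical zero-variance groups return
  p = 1 with a warning.

## Synthetic imaging and tracking

Rendering uses an isotropic Gaussian PSF stand-in (unit-integral spots;
separable 3D Gaussian sampled on a 45-plane z-grid for confocal-like
stacks). Only relative intensities are meaningful; there is no optics
model. Total fluorescence per GUV is the plane-and-pixel sum after
per-pixel background subtraction clamped at zero; concentration groups use
the thresholds <100 (low), 100–175 (medium, boundaries inclusive by the
literal reading of "between"), >175 a.u. (high).

Detection thresholds connected components and takes an intensity-weighted
centroid with the threshold level subtracted from the weights (subtracting
the cut level removes most of the mask-truncation bias; ≤0.05 px residual
on noise-free spots). Linking is greedy nearest-neighbour per consecutive
frame pair with a hard displacement gate, ties broken by smaller
displacement then lower track id, no gap closing — adequate for the
few-particle, always-in-focus fields simulated here, and a documented
simplification versus global-assignment trackers.

## What the generator emulates — and what it does not

Emulated: trajectory statistics of ~1.2 µm motors at 5 fps/60 s (frame
count, localization noise, XY projection of 3D motion); sub-diffusion of
confined passive motors and its fuel-, size- and crowding-dependence;
fuel permeation kinetics across plain and porated membranes; relative
z-stack fluorescence as a particle-count readout.

Not emulated: microscopic diffusiophoresis (no concentration-field PDE;
propulsion is phenomenological), membrane deformation or adhesion,
inter-particle hydrodynamics (crowding is mean-field), optics (diffraction,
refractive mismatch, confocal noise statistics), absolute fluorescence
calibration. Passing tests therefore demonstrate that the analysis chain
recovers the statistical structure this model family produces — not that
the model mechanism is the unique explanation of the laboratory
observations. In particular, the sub-diffusive exponent emerges here from
deep drag suppression *plus* measurement noise; distinguishing that from
genuine anti-persistent dynamics in real data would need the
noise-corrected estimators this package deliberately leaves out of scope.

## Numerical choices and degenerate inputs

- Euler–Maruyama at dt = 0.01 s, 20 substeps per frame; per-particle
  noise streams from `default_rng((master_seed, particle_index))`, so
  ensembles are reproducible and byte-identical across runs regardless of
  ensemble size.
- Initial positions uniform in the central sphere of radius R/4 (motors
  are tracked starting near the GUV centre); initial orientations uniform
  on the sphere.
- Mobility gap clamped at 0; reflection clamps pathological overshoot to
  the wall radius; orientation renormalized every step (unit within 1e-9).
- MSD of a <2-frame trajectory, empty ensembles, fits with <4 (power-law)
  or <3 (linear) lags in the window, and non-positive MSD in a log-log fit
  window all raise `ValueError` rather than returning NaN.
- `msd_at` uses nearest-grid lookup (exact on-grid).

## Calibrated defaults (frozen)

| parameter | value | meaning |
|---|---|---|
| D_T0 | 0.2 µm²/s | bulk passive diffusion |
| D_R | 2.0 s⁻¹ | effective propulsion-axis decorrelation |
| v_max | 0.79 µm/s | saturating propulsion speed |
| K_fuel | 0.1% v/v | fuel half-saturation (≈ catalase K_M) |
| λ_wall | 45 µm | wall-coupling length (interior-spanning drag) |
| m_min | 0.02 | mobility floor at membrane contact |
| σ_loc | 0.08 µm | static localization error per axis |
| P | 1.1×10⁻⁶ m/s | bilayer permeability to H₂O₂ (×100 with pores) |

The wall/noise parameters were calibrated once against the confined
passive exponent and the fuel-map parameters once against the D_T doubling
and the 3.4% exponent, then frozen; all reported numbers (tests,
`scripts/acceptance.py`, `analysis/`) are computed with these values.

## Known limitations

- The size-group α ordering saturates at high fuel: active motion masks
  the drag differences between 14–24 and 25–34 µm compartments (the
  ordering test runs at low fuel). The real data show an analogous
  saturation in the small-size group.
- Absolute confined MSD values are below the laboratory ones (e.g.
  MSD(10 s) ~2 µm² vs ~8–10 µm² in the crowding analysis); the
  calibration targets exponents and fold changes, not absolute MSD scale.
- Greedy linking will swap identities for dense, fast-crossing particles;
  it is used here only in sparse fields.
- The t-test treats particles as independent units; motors sharing a GUV
  are weakly dependent through the common compartment.
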