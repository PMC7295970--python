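# nanocav

Cavitation-bubble growth and collapse analysis for molecular-dynamics-style
particle trajectories of water and gelatin-like hydrogel.

Gelatin hydrogels are standard brain-tissue simulants, and the damage done
by collapsing cavitation bubbles in such soft matter is set by a handful of
continuum quantities — the threshold (most negative) pressure a nanobubble
needs to grow, the viscosity-dominated collapse time, the damping of its
volume pulsation — that are measured from atomistic trajectories.
`nanocav` packages both sides of that comparison:

**Continuum models** (SI units, tension = negative pressure)

- Equilibrium threshold pressure of a stable bubble, `P_cav = −2S/R`, and
  its decomposition for a gel, `P_cav|gel = P_cav|liq + P_cav|network`.
- The Rayleigh–Plesset equation for the bubble radius `R(t)`,

  `R·R̈ + (3/2)Ṙ² + (4η/ρR)·Ṙ + (2σ/ρR) = −(P_ext − P_b)/ρ`,

  integrated with adaptive stiff-capable stepping and event detection on a
  configurable collapse threshold (default `R ≤ 0.01·R0`), plus the
  classical Rayleigh closed form `t_c = 0.915·R0·√(ρ/ΔP)` as an analytic
  oracle.
- The small-amplitude volume pulsation `m·V̈ + b·V̇ + k·V = 0` with the
  Strasberg constants `m = ρ/(4πR)`, `b = η/(πR³)` (viscous dissipation
  only) and its `k = 0` exponential relaxation `V(t) = C1·e^(−bt/m) + C2`.
- The Fisher homogeneous-nucleation relation
  `P ∝ [ln(N·kB·T·t/h)]^(−1/2)`: across 33 decades of waiting time the
  threshold moves by only ≈ 1.6×.

**Trajectory estimators** (dump units: Å, ps, amu, atm·Å³)

- Probe-sphere cavity detection on a periodic occupancy grid, surface
  triangulation, and the sphericity index `Ψ = π^(1/3)·(6V_c)^(2/3)/A_c`
  (1 for a sphere).
- Virial pressure `P = (Pxx + Pyy + Pzz)/(3V)` from per-atom stress×volume
  with periodic Voronoi per-atom volumes; density with the cavity volume
  excluded; smoothed threshold-pressure extraction; volumetric strain
  schedules; system-volume bookkeeping
  `V_system = V_water + V_network + V_bubble`.
- MSD with all time origins (FFT) and the one-sixth-slope diffusion
  coefficient; Green–Kubo shear viscosity
  `η = (V/kB·T)·∫⟨P_offdiag(0)P_offdiag(t)⟩dt` with block-averaged errors.

**Synthetic generators** with analytic ground truth (carved-cavity fluids,
radius-scheduled growth trajectories, Brownian walkers, Ornstein–Uhlenbeck
stress, damped series) make every estimator testable without running MD.

Media presets `water` (ρ = 1020 kg/m³, η = 0.321 mPa·s, σ = 0.0557 N/m,
R0 = 95.16 Å) and `gel` (ρ = 1050, η = 0.684, σ = 0.0976, R0 = 95.35 Å)
carry the measured properties of the two reference systems.

## Worked example

Collapse of the pre-carved ~95 Å bubble under a restored 10 MPa ambient
pressure, water versus gel:

```bash
$ nanocav analyze-collapse --pext 10 --out-dir collapse_out
{
  "pext_MPa": 10.0,
  "config_digest": "027358d3a503",
  "rp_collapse_time_water_ps": 86.56789827345122,
  "rp_collapse_time_gel_ps": 112.50266834216755,
  "collapse_time_ratio_gel_over_water": 1.2995887688851289
}
```

At this scale surface tension (which adds ~12 MPa of collapse drive at
R0 ≈ 95 Å) and viscosity nearly cancel for water — its 86.6 ps is close to
the inviscid, zero-σ Rayleigh estimate of 87.9 ps — while the ~2.1× more
viscous gel needs ~30 % longer than water under identical driving: the
collapse time is dominated by the viscosity of the medium.

The same comparison in the library:

```python
from nanocav import WATER, BubbleInitialState, PressureSchedule, solve_rp
sol = solve_rp(WATER, BubbleInitialState(radius0=95.16e-10),
               PressureSchedule.constant(10e6), horizon=1e-9)
print(sol.termination, sol.collapse_time)   # collapsed 8.656789827345122e-11
```

A synthetic growth trajectory, analysed end to end:

```bash
nanocav synth --kind growth --seed 2 --out growth.dump \
    --box 110 110 110 --r-start 40 --r-end 48 --duration 30 --frames 4
nanocav analyze-growth --traj growth.dump --out-dir growth_out
```

writes `cavity_radius.csv`, `sphericity.csv`, `density.csv` (with `# unit:`
headers) into `growth_out/`; the recovered radius series matches the
prescribed 40→48 Å schedule to a few percent at the default 2 Å grid.

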