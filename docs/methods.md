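# Methods

This note records the models implemented in `nanocav`, the numerical and
design choices behind them, what the synthetic generators do and do not
emulate, and the known limitations.

## Continuum bubble models

### Equilibrium threshold and network decomposition

A stable bubble of radius `R` in a liquid of surface tension `S` balances
`2S/R + P_cav = 0`, so the far-field pressure needed to hold it is
`P_cav = −2S/R` (tension, negative by our sign convention throughout).
For a gel the same balance holds with the gel surface tension, and the
difference `P_cav|gel − P_cav|liq` is interpreted as the pressure
equivalent of the extra strain energy stored in the polymer network
(`network_pressure`). With the preset media and their ~95 Å initial radii
these evaluate to −11.7 MPa (water) and −20.5 MPa (gel).

### Rayleigh–Plesset integration

`solve_rp` integrates

    R·R̈ + (3/2)·Ṙ² + (4η/ρR)·Ṙ + (2σ/ρR) = −(P_ext − P_b)/ρ

as a first-order system in (R, Ṙ) with `scipy.integrate.solve_ivp`
(LSODA, rtol 1e-8, radius atol 1e-12 m). Constant liquid properties and a
negligible internal pressure `P_b ≈ 0` are assumed — a nanobubble holds
too few vapor molecules to load its wall. Because Ṙ diverges as `R → 0`,
integration terminates by event detection when `R` crosses a configurable
*collapse fraction* of `R0` (default 1 %), and the event time is reported
as the collapse time. The inviscid, zero-σ limit has the classical
Rayleigh closed form `t_c = √(π/6)·Γ(5/6)/Γ(4/3)·R0·√(ρ/ΔP) ≈
0.914681·R0·√(ρ/ΔP)`, implemented separately as an oracle; the solver
reproduces it to better than 0.5 % across decades of (ρ, R0, ΔP).

The static equilibrium `P_ext = P_b − 2σ/R0` is a *saddle point* of the
dynamics for σ > 0: linearising gives a growth rate `√(2σ/ρR0³)`
(≈ 3.6×10¹¹ s⁻¹ for the water preset), so any perturbation — including
floating-point rounding — would escape within a few collapse-time scales.
The right-hand side therefore evaluates the forcing and surface terms with
bitwise-identical expressions, making the fixed point exact in floating
point; the "equilibrium hold" test exercises exactly this construction and
should not be read as a statement about stability under perturbation.

### Damped volume pulsation

Small-amplitude pulsation of a (possibly non-spherical) bubble is modelled
on the volume, `m·V̈ + b·V̇ + k·V = 0`. Of the four dissipation channels
(viscous, thermal, radiation, phase change) only the viscous one survives
in an isothermal, radiation-free, near-empty-bubble setting, giving
`b = η/(πR³)`. The source model leaves the inertia constant unstated; we
adopt the Strasberg volume-pulsation inertia `m = ρ/(4πR)`, the unique
standard choice dimensionally consistent with that `b`, which yields the
volume relaxation rate `b/m = 4η/(ρR²)` (1.39×10¹⁰ s⁻¹ for the water
preset at 95.16 Å; the gel value is ≈ 2.1× larger — collagen damps the
pulsation roughly at the viscosity ratio). The stiffness `k` is
proportional to the internal gas pressure, which is negligible here, so
`k = 0` by default and `k` is exposed as an optional input with no implied
constant.

With `k = 0` the equation integrates to `V(t) = C1·e^(−bt/m) + C2`,
`C1 = −V̇0·m/b`, `C2 = V0 + V̇0·m/b` (`V = V0 + V̇0·t` in the limit
`b → 0`). The solution object carries analytic first and second
derivatives so the residual `m·V̈ + b·V̇` can be checked directly; radius
is exposed as `(3V/4π)^(1/3)`. Note the model is written for volume — a
radius relaxation of the same exponential form is only approximate.

The printed damping ratio `δ = b/√(k/m)` of the source is not
dimensionless and is inconsistent with the `√(1−δ²/4)` factor of its own
frequency formula; interpreting the intended quantity as `(b/m)/√(k/m)`
(= 2ζ, twice the textbook ratio) reconciles the two. The implementation
reports the verbatim quantity (`damping_ratio_delta`), the standard
`ζ = b/(2√(km))` (`damping_ratio`), and computes the underdamped natural
frequency as `f_n = (1/2π)·√(k/m)·√(1−ζ²)`, returning `None` when
overdamped or `k = 0`.

### Fisher nucleation-time relation

Under homogeneous nucleation theory the critical cavitation pressure
depends on the allowed waiting time `t` only through
`P ∝ [ln(N·kB·T·t/h)]^(−1/2)`; the surface-tension prefactor cancels in
ratios. With `N = 6.022×10²³` molecules and `T = 300 K` (CODATA `kB`,
`h`), the ratio between `t = 10⁻¹⁵ s` (an atomic vibration) and
`t = 10¹⁸ s` (the age of the universe) evaluates to 1.59 — waiting time is
almost irrelevant to the threshold, which motivates treating strain-rate
effects as a separate, dynamic phenomenon.

## Trajectory estimators

Trajectory data use the MD dump conventions: Å, ps, amu, per-atom virial
stress as stress×volume in atm·Å³ (pressure output in MPa via
0.101325 MPa/atm), orthorhombic periodic boxes only (triclinic cells are
rejected at the reader). Per-atom stress is stored in the *pressure* sign
convention — tension makes the global pressure negative; raw LAMMPS
`stress/atom` output has the opposite sign and must be negated upstream.

### Cavity detection and geometry

Space is sampled on a regular grid (default 2 Å; the actual spacing
divides each box edge exactly, and at least 3 voxels per edge are
required). A voxel is *core-empty* if its centre lies farther than the
probe radius (default 3 Å, about a water molecule) from every particle,
with periodic minimum-image distances from a KD-tree. The core is then
dilated by the probe radius (periodic Euclidean distance transform): a
point belongs to the cavity iff some probe sphere covering it contains no
particle. Without this dilation the detected void would be uniformly one
probe radius too small. Connected components are labelled with
periodic-aware 6-connectivity; the largest component above a minimum
volume is the cavity, the others are counted as secondary voids
(instantaneously nucleated tiny bubbles). The minimum reported volume
defaults to 500 Å³ (≈ 17 water molecules): a design calibration on the
generator's homogeneous fluid showed thermal noise voids after dilation
stay well below this, while any physically meaningful bubble is far above
it.

The cavity surface is triangulated by marching cubes on the signed
distance field (distance-to-core − probe radius), Gaussian-smoothed with a
fixed *physical* width (default 3 Å): the voxelised core boundary makes
the raw field bumpy, inflating the mesh area by the staircase artifact,
and a width tied to voxels rather than Å would make the measurement
non-convergent under grid refinement. Volume is the divergence-theorem sum
over oriented triangles, area the triangle sum, and
`Ψ = π^(1/3)·(6V_c)^(2/3)/A_c` with `R_eff = (3V_c/4π)^(1/3)` (both the
mesh radius and `R_eff` are available; `R_eff` is the default radius
measure, and the growth series is exactly volume-consistent with it).

Known property: on point particles the rolling-probe surface penetrates
the pockets between surface atoms by a fraction of an ångström, so as the
grid is refined below ~2 Å the measured volume of a carved 50 Å void
plateaus ~5 % *above* the geometric carve volume rather than converging to
it exactly. At the default spacing the estimate is within ~1 %, and
halving the spacing from coarse grids converges toward the carve volume;
the residual offset is a property of the surface definition (shared by
probe-based surface reconstruction generally), not of the grid.

### Virial pressure, density, thresholds, bookkeeping

`global_pressure` sums the three diagonal per-atom stress×volume
components over (optionally a species- or mask-selected subset of) atoms
and divides by 3× the summed per-atom volumes — the per-atom volumes come
from a periodic Voronoi tessellation (`voronoi_volumes`), computed by
tiling the frame with its 26 periodic images and measuring the cells of
the central copy (qhull has no periodic mode; the tiled cells are exactly
the periodic ones and sum to the box volume to 1e-6). Density excludes
the cavity volume from the denominator, since a frame holding a large void
is otherwise not at its bulk density. Threshold pressure is the global
minimum of a centred moving average (default 1 ps window; the window is
rounded to an odd sample count), ties broken earliest, with a boundary
flag when the minimum sits at the trace edge. Volumetric strain schedules
are linear in time (`ε_v = rate·t`, constant volume-expansion rate, not
exponential/true strain — so equal rate×duration products give equal final
expansion, e.g. 6.7×10⁹ s⁻¹ × 60 ps ≈ 1.35×10¹⁰ s⁻¹ × 30 ps). The volume
bookkeeping `V_bubble = V_system − V_water − V_network` closes to 0.1 %
or errors out.

### Transport

MSD averages over all time origins via the standard FFT decomposition
(O(T log T) per particle, verified against the O(T²) double loop) and
requires unwrapped coordinates or image flags; lags beyond half the span
are not reported. The diffusion coefficient is one sixth of the
least-squares MSD slope over a configurable window (default 20–80 % of
the maximum lag — the early lags are ballistic/correlated, the late ones
origin-starved). The log–log slope α over the same window is attached as
a diagnostic; |α − 1| > 0.3 flags non-diffusive (e.g. ballistic, α = 2)
behaviour.

Green–Kubo viscosity integrates the origin- and component-averaged
autocorrelation of the off-diagonal pressure components to a cutoff
(trapezoid), scaled by `V/kB·T`. The cutoff defaults to 10× the
integrated autocorrelation time (ACF integral to its first zero crossing
over the variance); the series must be at least 10× the cutoff long. The
standard error comes from ≥ 5 contiguous block estimates.

## Synthetic generators

The generators emulate the *statistical structure* of MD output, not its
physics: monodisperse 18 amu pseudo-water beads (the estimators consume
only positions, masses, stress), no interatomic forces, no pressure–density
coupling. Ground truth sufficient to predict every downstream estimate
analytically is always returned with the data, and identical seeds give
bit-identical output.

- **Fluid with cavity** — beads placed by rejection sampling at the target
  density outside a carved sphere/ellipsoid, with a minimum-distance core
  of 2.4 Å emulating the correlation hole of a liquid. This matters: pure
  Poisson placement at 1.02 g/cm³ leaves ~2 % of space farther than 3 Å
  from every bead, which would riddle a nominally homogeneous fluid with
  probe-scale voids and defeat cavity detection. A jittered simple-cubic
  lattice mode exists for exact-volume tests (plain lattices degenerate
  the Voronoi tessellation). Optional isotropic per-atom stress realises a
  requested global pressure exactly. Bead count is rounded so the realised
  density is within 1 % of the target.
- **Growth trajectory** — one base fluid; per scheduled time, beads inside
  the scheduled radius are dropped and the rest get 0.3 Å Gaussian jitter
  (thermal interface roughness). Ids are base indices, so identity is
  maintained and the always-retained subset supports MSD. The schedule can
  be an RP solution, closing the loop model → trajectory → measured radius.
- **Brownian walkers** — Gaussian steps of variance 2D·dt per axis,
  unwrapped coordinates.
- **OU stress** — exact-discretisation Ornstein–Uhlenbeck, stationary from
  the first sample, variance s², correlation time τ; implied viscosity
  `(V/kB·T)·s²·τ` (white-noise invariant: depends on s²·τ only).
- **Damped series** — `C1·e^(−λt)·cos(2πft) + offset +` noise.

What passing tests on these do *not* show about real MD data: pressure
traces here have no hydrodynamic feedback on the cavity, interfaces have
no molecular layering or tension, the gel network is absent (the network
volume enters only as bookkeeping input), and stress fluctuations are
exactly Gaussian-Markov. Estimator correctness and parameter recovery are
validated; force-field-dependent values (measured viscosities, thresholds
at −93/−101 MPa, etc.) are inputs, not outputs.

## Problem sizes and defaults

The validation suite runs on desk-scale inputs chosen to keep statistical
error comfortably inside each tolerance: carved-cavity frames of
(120 Å)³ (~41 k beads) and one full (211×211×165 Å) study-geometry box
(~233 k beads); Brownian recovery at 1000 walkers × 1000 steps (D error
~1 %); Green–Kubo on 3 × 100 k-step OU components (η scatter ~5 % against
a 15 % band); Voronoi conservation on 150-bead frames with full 27-image
tiling. Default analysis parameters: grid 2 Å, probe 3 Å, minimum void
500 Å³, smoothing window 1 ps, MSD fit window 20–80 %, GK cutoff 10× the
autocorrelation time, RP collapse fraction 1 %.

## Limitations

- Orthorhombic periodic boxes only; no triclinic support.
- Single-cavity focus: per-frame largest void plus a count of secondary
  voids; no multi-bubble tracking across frames.
- The RP model omits thermal, radiation and phase-change damping, acoustic
  forcing, non-spherical corrections and bubble–bubble interaction.
- Surface tension is an input parameter; it is not estimated from stress
  profiles.
- A cavity percolating the periodic box in any direction cannot be meshed
  and raises a mesh error (its voxel volume is still available).
- The presets' initial radii follow the measured ≈ 95 Å values even though
  the systems are nominally built around a 5 nm (50 Å) carved bubble; the
  two describe different stages (post-growth vs as-built) and the 95 Å
  values are used wherever a preset radius is needed.
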