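"""Continuum bubble-dynamics models.

This module implements the spherical-bubble continuum models used to
interpret nanoscale cavitation in water and gelatin-like hydrogel:

* the equilibrium (threshold) cavitation pressure −2σ/R of a stable bubble,
  and its decomposition into a liquid part plus a network part for a gel;
* the Rayleigh–Plesset (RP) equation for the radius R(t) of a spherical
  bubble in an incompressible viscous liquid,

  .. math::

     R\\ddot R + \\tfrac{3}{2}\\dot R^2 + \\frac{4\\eta}{\\rho R}\\dot R
     + \\frac{2\\sigma}{\\rho R} = -\\frac{P_\\mathrm{ext} - P_b}{\\rho},

  integrated with adaptive stiff-capable stepping and event-based collapse
  detection;
* the classical Rayleigh closed-form collapse time of an empty cavity in an
  inviscid, zero-surface-tension liquid (used as an analytic oracle);
* the small-amplitude volume-pulsation model m V̈ + b V̇ + k V = 0 with the
  Strasberg constants m = ρ/(4πR), b = η/(πR³), and its k = 0 exponential
  relaxation solution;
* the Fisher homogeneous-nucleation relation, by which the critical
  cavitation pressure depends on waiting time only as
  P ∝ [ln(N·kB·T·t/h)]^(−1/2).

All quantities are SI.  Tension is represented as negative pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import gamma as _gamma

from .constants import BOLTZMANN, PLANCK
from .media import FluidMedium

__all__ = [
    "BubbleInitialState",
    "PressureSchedule",
    "RPSolution",
    "OscillationModel",
    "DampedVolumeSolution",
    "NucleationSetting",
    "equilibrium_cavitation_pressure",
    "network_pressure",
    "rayleigh_collapse_time",
    "RAYLEIGH_FACTOR",
    "solve_rp",
    "oscillation_parameters",
    "damped_volume_relaxation",
    "fisher_threshold_ratio",
]


# --------------------------------------------------------------------------
# equilibrium / threshold pressure
# --------------------------------------------------------------------------

def equilibrium_cavitation_pressure(medium: FluidMedium, radius: float) -> float:
    """Far-field pressure balancing a stable bubble of the given radius.

    From the static balance 2S/R + P_cav = 0, the required far-field pressure
    is ``-2 * surface_tension / radius`` — negative, i.e. tension.  The same
    formula applies to a gel medium with the gel surface tension.

    Parameters
    ----------
    medium : FluidMedium
        Supplies the surface tension S (N/m).
    radius : float
        Stable bubble radius R in metres; must be positive.

    Returns
    -------
    float
        Equilibrium cavitation pressure in Pa (negative for S > 0).
    """
    if not radius > 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    return -(2.0 * medium.surface_tension / radius)


def network_pressure(p_cav_gel: float, p_cav_liq: float) -> float:
    """Pressure equivalent of the gel network's additional strain energy.

    The gel threshold decomposes as P_cav|gel = P_cav|liq + P_cav|network,
    so the network contribution is simply the difference of the two
    thresholds (both in Pa, tension negative).
    """
    return p_cav_gel - p_cav_liq


# --------------------------------------------------------------------------
# Rayleigh–Plesset
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BubbleInitialState:
    """Initial condition for the RP integration.

    radius0 : initial radius R(0) in m (> 0).
    radial_velocity0 : initial wall speed dR/dt(0) in m/s.
    internal_pressure : bubble internal pressure P_b in Pa. Defaults to 0 —
        a nanobubble holds too few vapor molecules to exert meaningful
        pressure on its wall.
    """

    radius0: float
    radial_velocity0: float = 0.0
    internal_pressure: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius0 > 0:
            raise ValueError(f"radius0 must be > 0, got {self.radius0}")


class PressureSchedule:
    """External far-field pressure P_ext(t), constant or sampled.

    Use :meth:`constant` or :meth:`sampled` to construct.  A sampled schedule
    interpolates linearly and is only defined on its sampled time span.
    """

    def __init__(self, times: Optional[np.ndarray], values: np.ndarray):
        if times is None:
            self.mode = "constant"
            self.times = None
            self.values = float(values)
        else:
            times = np.asarray(times, dtype=float)
            values = np.asarray(values, dtype=float)
            if times.ndim != 1 or times.shape != values.shape:
                raise ValueError("times and values must be 1-D and equal length")
            if times.size < 2 or np.any(np.diff(times) <= 0):
                raise ValueError("sampled times must be strictly increasing (>= 2)")
            self.mode = "sampled"
            self.times = times
            self.values = values

    @classmethod
    def constant(cls, pressure: float) -> "PressureSchedule":
        return cls(None, pressure)

    @classmethod
    def sampled(cls, times: Sequence[float], values: Sequence[float]) -> "PressureSchedule":
        return cls(np.asarray(times), np.asarray(values))

    def covers(self, t0: float, t1: float) -> bool:
        if self.mode == "constant":
            return True
        return self.times[0] <= t0 and self.times[-1] >= t1

    def __call__(self, t):
        if self.mode == "constant":
            return self.values if np.isscalar(t) else np.full_like(np.asarray(t, float), self.values)
        return np.interp(t, self.times, self.values)


@dataclass
class RPSolution:
    """Integrated bubble radius history with collapse diagnostics.

    termination is one of ``"collapsed"``, ``"horizon_reached"`` or
    ``"solver_failure"``; ``collapse_time`` (s) is present iff collapsed.
    """

    times: np.ndarray
    radius: np.ndarray
    radial_velocity: np.ndarray
    termination: str
    collapse_time: Optional[float] = None


#: Prefactor of the Rayleigh collapse time, sqrt(pi/6)*Gamma(5/6)/Gamma(4/3).
RAYLEIGH_FACTOR = float(math.sqrt(math.pi / 6.0) * _gamma(5.0 / 6.0) / _gamma(4.0 / 3.0))


def rayleigh_collapse_time(density: float, radius0: float, delta_p: float) -> float:
    """Closed-form collapse time of an empty cavity in an inviscid liquid.

    t_c = 0.914681 · R0 · sqrt(ρ/ΔP), the classical Rayleigh result for
    η = 0, σ = 0 and constant driving pressure ΔP = P_ext − P_b > 0.
    Serves as the analytic oracle for :func:`solve_rp` in that limit.
    """
    for name, v in (("density", density), ("radius0", radius0), ("delta_p", delta_p)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return RAYLEIGH_FACTOR * radius0 * math.sqrt(density / delta_p)


def solve_rp(
    medium: FluidMedium,
    init: BubbleInitialState,
    schedule: PressureSchedule,
    horizon: float,
    *,
    collapse_fraction: float = 0.01,
    rtol: float = 1e-8,
    atol_radius: float = 1e-12,
    method: str = "LSODA",
    max_step: Optional[float] = None,
) -> RPSolution:
    """Integrate the Rayleigh–Plesset equation up to ``horizon`` seconds.

    Integration stops when R falls below ``collapse_fraction * radius0``
    (default 1 %), recording the event time as ``collapse_time``; the
    singularity at R → 0 makes integrating to exactly zero impossible.
    Stepping is adaptive (LSODA, stiff-capable) with event detection on the
    collapse threshold; the wall velocity diverges near collapse, so the
    final approach is resolved by the event root-finder rather than by
    shrinking fixed steps.

    Notes
    -----
    The surface-tension term and the driving term are evaluated with
    identical floating-point expressions, so a bubble started exactly at the
    equilibrium pressure −2σ/R0 (an unstable fixed point for σ > 0) has a
    bitwise-zero right-hand side and holds its radius indefinitely.
    """
    if not horizon > 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    if not 0 < collapse_fraction < 1:
        raise ValueError("collapse_fraction must lie in (0, 1)")
    if not schedule.covers(0.0, horizon):
        raise ValueError("pressure schedule does not cover the integration window")

    rho = medium.density
    eta = medium.viscosity
    sigma = medium.surface_tension
    r0 = init.radius0
    pb = init.internal_pressure
    r_min = collapse_fraction * r0

    def rhs(t, y):
        r, v = y
        # numerator in Pa: -(Pext - Pb) - 2σ/R - 4ηv/R; then /ρ, minus inertia terms
        drive = -(schedule(t) - pb)
        num = drive - (2.0 * sigma / r) - (4.0 * eta * v / r)
        acc = (num / rho - 1.5 * v * v) / r
        return (v, acc)

    def collapse_event(t, y):
        return y[0] - r_min

    collapse_event.terminal = True
    collapse_event.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        (r0, init.radial_velocity0),
        method=method,
        rtol=rtol,
        atol=(atol_radius, 1e-6),
        events=collapse_event,
        max_step=np.inf if max_step is None else max_step,
        dense_output=False,
    )

    times = sol.t
    radius = sol.y[0]
    velocity = sol.y[1]
    collapse_time = None
    if sol.status == 1 and sol.t_events[0].size:  # event hit
        collapse_time = float(sol.t_events[0][0])
        termination = "collapsed"
        # ensure the event point terminates the reported trace
        if times[-1] != collapse_time:
            times = np.append(times, collapse_time)
            radius = np.append(radius, sol.y_events[0][0][0])
            velocity = np.append(velocity, sol.y_events[0][0][1])
    elif sol.status == 0:
        termination = "horizon_reached"
    else:
        termination = "solver_failure"

    keep = radius > 0
    return RPSolution(
        times=times[keep],
        radius=radius[keep],
        radial_velocity=velocity[keep],
        termination=termination,
        collapse_time=collapse_time,
    )


# --------------------------------------------------------------------------
# damped volume pulsation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OscillationModel:
    """Constants of the volume-pulsation equation m V̈ + b V̇ + k V = 0.

    inertia_m (kg·m⁻⁴), damping_b (kg·m⁻⁴·s⁻¹) and stiffness_k
    (kg·m⁻⁴·s⁻²) follow the Strasberg volume formulation.  Derived fields:

    relaxation_rate
        b/m = 4η/(ρR²) (s⁻¹), the exponential decay rate of the k = 0
        volume relaxation.
    natural_frequency
        f_n = (1/2π)·√(k/m)·√(1−ζ²) in Hz for an underdamped bubble
        (k > 0, ζ < 1); ``None`` when k = 0 or the motion is overdamped.
    damping_ratio_delta
        The quantity b/√(k/m) exactly as the source model writes it.  As
        printed it is not dimensionless; the standard dimensionless ratio
        ζ = b/(2√(km)) is reported alongside as ``damping_ratio`` and is
        what the frequency formula uses.
    """

    inertia_m: float
    damping_b: float
    stiffness_k: float = 0.0

    def __post_init__(self) -> None:
        if not self.inertia_m > 0:
            raise ValueError("inertia_m must be > 0")
        if self.damping_b < 0:
            raise ValueError("damping_b must be >= 0")
        if self.stiffness_k < 0:
            raise ValueError("stiffness_k must be >= 0")

    @property
    def relaxation_rate(self) -> float:
        return self.damping_b / self.inertia_m

    @property
    def damping_ratio(self) -> Optional[float]:
        """Standard dimensionless damping ratio ζ = b/(2√(km)); None if k = 0."""
        if self.stiffness_k == 0:
            return None
        return self.damping_b / (2.0 * math.sqrt(self.stiffness_k * self.inertia_m))

    @property
    def damping_ratio_delta(self) -> Optional[float]:
        """δ = b/√(k/m), reported verbatim from the source model; None if k = 0."""
        if self.stiffness_k == 0:
            return None
        return self.damping_b / math.sqrt(self.stiffness_k / self.inertia_m)

    @property
    def natural_frequency(self) -> Optional[float]:
        if self.stiffness_k == 0:
            return None
        zeta = self.damping_ratio
        if zeta >= 1.0:  # overdamped: no real oscillation frequency
            return None
        omega0 = math.sqrt(self.stiffness_k / self.inertia_m)
        return omega0 / (2.0 * math.pi) * math.sqrt(1.0 - zeta * zeta)


def oscillation_parameters(
    medium: FluidMedium, radius: float, stiffness_k: float = 0.0
) -> OscillationModel:
    """Volume-pulsation constants for a bubble of the given radius.

    Only viscous dissipation is retained (b ≅ b_vis = η/(πR³)): at constant
    temperature the thermal term vanishes, there is no acoustic radiation at
    these scales, and the near-empty bubble has negligible phase-change
    dissipation.  The inertia constant is the Strasberg value m = ρ/(4πR).
    The stiffness, proportional to the internal gas pressure, defaults to
    zero (near-vacuum bubble); pass ``stiffness_k`` to study forced gas
    stiffness.
    """
    if not radius > 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if stiffness_k < 0:
        raise ValueError(f"stiffness_k must be >= 0, got {stiffness_k}")
    b = medium.viscosity / (math.pi * radius**3)
    m = medium.density / (4.0 * math.pi * radius)
    return OscillationModel(inertia_m=m, damping_b=b, stiffness_k=stiffness_k)


@dataclass
class DampedVolumeSolution:
    """k = 0 volume relaxation V(t) with analytic derivatives.

    ``radius`` exposes the equivalent spherical radius (3V/4π)^(1/3).
    """

    times: np.ndarray
    volume: np.ndarray
    dvdt: np.ndarray
    d2vdt2: np.ndarray

    @property
    def radius(self) -> np.ndarray:
        return (3.0 * self.volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def damped_volume_relaxation(
    model: OscillationModel, v0: float, vdot0: float, times: Sequence[float]
) -> DampedVolumeSolution:
    """Exponential relaxation of the bubble volume in the k = 0 regime.

    With vanishing stiffness the pulsation equation reduces to
    m V̈ + b V̇ = 0, whose solution is V(t) = C1·e^(−bt/m) + C2 with
    C1 = −vdot0·m/b and C2 = v0 + vdot0·m/b fixed by the initial volume and
    volume rate.  In the undamped limit b → 0 the solution degenerates to
    uniform expansion V(t) = v0 + vdot0·t.
    """
    if model.stiffness_k != 0:
        raise ValueError("exponential relaxation requires stiffness_k == 0")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    b_over_m = model.relaxation_rate
    if b_over_m == 0.0:
        v = v0 + vdot0 * t
        return DampedVolumeSolution(t, v, np.full_like(t, vdot0), np.zeros_like(t))
    c1 = -vdot0 / b_over_m
    c2 = v0 + vdot0 / b_over_m
    decay = np.exp(-b_over_m * t)
    v = c1 * decay + c2
    dv = -b_over_m * c1 * decay
    d2v = b_over_m**2 * c1 * decay
    return DampedVolumeSolution(t, v, dv, d2v)


# --------------------------------------------------------------------------
# Fisher nucleation-time relation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleationSetting:
    """Arguments of the homogeneous-nucleation waiting-time relation.

    molecule_count : number of molecules N (default one mole's worth).
    temperature : K.
    waiting_time : allowed nucleation waiting time t in seconds.
    """

    waiting_time: float
    molecule_count: float = 6.022e23
    temperature: float = 300.0

    def __post_init__(self) -> None:
        for name, v in (
            ("waiting_time", self.waiting_time),
            ("molecule_count", self.molecule_count),
            ("temperature", self.temperature),
        ):
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    def log_attempt_factor(self) -> float:
        """ln(N·kB·T·t/h); must exceed 0 for a defined threshold."""
        arg = self.molecule_count * BOLTZMANN * self.temperature * self.waiting_time / PLANCK
        if arg <= 1.0:
            raise ValueError(
                f"ln argument N·kB·T·t/h = {arg:.3g} <= 1: threshold undefined"
            )
        return math.log(arg)


def fisher_threshold_ratio(
    setting1: NucleationSetting, setting2: NucleationSetting
) -> float:
    """Ratio P(t1)/P(t2) of homogeneous-cavitation critical pressures.

    Under the nucleation-time relation P ∝ [ln(N·kB·T·t/h)]^(−1/2), the
    critical pressure at the shorter waiting time t1 exceeds that at the
    longer t2 by √(ln(N·kB·T·t2/h)/ln(N·kB·T·t1/h)); the surface-tension
    prefactor cancels.  Across the 33 decades from an atomic vibration
    period (1e−15 s) to the age of the universe (1e18 s) the ratio is only
    ≈ 1.6 — waiting time barely moves the threshold.

    Both settings must share N and T.
    """
    if setting1.molecule_count != setting2.molecule_count:
        raise ValueError("settings must share molecule_count")
    if setting1.temperature != setting2.temperature:
        raise ValueError("settings must share temperature")
    l1 = setting1.log_attempt_factor()
    l2 = setting2.log_attempt_factor()
    return math.sqrt(l2 / l1)
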