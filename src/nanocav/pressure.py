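"""Virial pressure, density, threshold extraction and volume bookkeeping.

The global pressure of a frame follows the per-atom virial recipe

    P = (Pxx + Pyy + Pzz) / (3 × V),

where Pαα sums the per-atom stress×volume components (atm·Å³) over all
atoms and V sums the per-atom (Voronoi) volumes.  Tension is negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .constants import AMU_TO_G, A3_TO_CM3, ATM_TO_MPA
from .cavity import CavityMetrics
from .frames import ParticleFrame, ScalarTimeSeries

__all__ = [
    "global_pressure",
    "density_excluding_cavity",
    "ThresholdResult",
    "threshold_pressure",
    "volume_strain_schedule",
    "VolumeDecomposition",
    "volume_decomposition",
]


def global_pressure(frame: ParticleFrame, selection: Optional[np.ndarray] = None) -> float:
    """Virial pressure of a frame in MPa (tension negative).

    Parameters
    ----------
    frame : ParticleFrame
        Must carry ``per_atom_stress`` (atm·Å³, components xx yy zz xy xz yz)
        and ``per_atom_volume`` (Å³).
    selection : array-like, optional
        Boolean mask or species label restricting the sum to a subset of
        atoms (e.g. water only, when deformation is applied to water alone).

    Raises
    ------
    ValueError
        Naming the absent per-atom field if stress or volume is missing.
    """
    if frame.per_atom_stress is None:
        raise ValueError("frame has no per_atom_stress; cannot compute virial pressure")
    if frame.per_atom_volume is None:
        raise ValueError("frame has no per_atom_volume; cannot compute virial pressure")
    stress = frame.per_atom_stress
    vol = frame.per_atom_volume
    if selection is not None:
        if isinstance(selection, str):
            if frame.species is None:
                raise ValueError("species selection requested but frame has no species")
            mask = frame.species == selection
        else:
            mask = np.asarray(selection, dtype=bool)
        stress = stress[mask]
        vol = vol[mask]
        if stress.shape[0] == 0:
            raise ValueError("selection matches no atoms")
    trace = stress[:, 0].sum() + stress[:, 1].sum() + stress[:, 2].sum()
    p_atm = trace / (3.0 * vol.sum())
    return float(p_atm * ATM_TO_MPA)


def density_excluding_cavity(
    frame: ParticleFrame, cavity: Union[CavityMetrics, float, None]
) -> float:
    """Mass density in g/cm³ with the cavity volume removed from the box.

    A frame holding a large void is not at its bulk density unless the
    empty volume is excluded from the denominator.  ``cavity`` may be a
    :class:`CavityMetrics`, a volume in Å³, or ``None``/0 for the ordinary
    bulk density.
    """
    v_c = 0.0
    if cavity is not None:
        v_c = cavity.volume_c if isinstance(cavity, CavityMetrics) else float(cavity)
    v_box = frame.box.volume
    if v_c >= v_box:
        raise ValueError(f"cavity volume {v_c} Å³ >= box volume {v_box} Å³")
    mass_g = frame.total_mass * AMU_TO_G
    return mass_g / ((v_box - v_c) * A3_TO_CM3)


@dataclass
class ThresholdResult:
    """Minimum of a smoothed pressure trace.

    ``boundary_minimum`` flags a minimum at the first or last smoothed
    sample (a monotone trace), where the true extremum may lie outside the
    observed window.
    """

    value: float  # MPa
    time: float  # ps
    boundary_minimum: bool
    window: float  # ps actually used
    smoothed: ScalarTimeSeries


def threshold_pressure(series: ScalarTimeSeries, window: float = 1.0) -> ThresholdResult:
    """Threshold (most negative) pressure of a trace after smoothing.

    A centred moving average of the stated window (default 1 ps) removes
    thermal pressure fluctuations; the global minimum of the smoothed trace
    and its time are returned, ties broken by earliest time.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 samples")
    t = series.times
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("threshold extraction requires uniform sampling")
    k = max(1, int(round(window / dt[0])))
    if k % 2 == 0:
        k += 1
    if k > len(series):
        raise ValueError(
            f"smoothing window {window} ps ({k} samples) exceeds series length {len(series)}"
        )
    kernel = np.ones(k) / k
    smooth_vals = np.convolve(series.values, kernel, mode="valid")
    half = k // 2
    smooth_t = t[half : len(t) - half] if half else t
    smoothed = ScalarTimeSeries(smooth_t, smooth_vals, unit=series.unit, name=series.name + "_smoothed")
    imin = int(np.argmin(smooth_vals))  # argmin returns the first (earliest) tie
    return ThresholdResult(
        value=float(smooth_vals[imin]),
        time=float(smooth_t[imin]),
        boundary_minimum=imin in (0, len(smooth_vals) - 1),
        window=k * float(dt[0]),
        smoothed=smoothed,
    )


def volume_strain_schedule(rate: float, duration: float, n_points: int = 101) -> ScalarTimeSeries:
    """Volumetric strain history under a constant volume-expansion rate.

    ε_v(t) = rate · t (linear in time), with ``rate`` in s⁻¹ and
    ``duration`` in ps.  The final strain is ``series.values[-1]``; equal
    rate×duration products (e.g. X for 60 ps vs 2X for 30 ps) reach the
    same percentage of volume expansion.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if duration == 0:
        return ScalarTimeSeries(np.array([0.0]), np.array([0.0]), unit="", name="volume_strain")
    t = np.linspace(0.0, duration, n_points)
    return ScalarTimeSeries(t, rate * t * 1e-12, unit="", name="volume_strain")


@dataclass
class VolumeDecomposition:
    """System-volume bookkeeping V_system = V_water + V_network + V_bubble (Å³)."""

    v_system: float
    v_water: float
    v_network: float
    v_bubble: float

    #: relative accounting tolerance on the closure of the decomposition
    TOLERANCE = 1e-3

    def __post_init__(self) -> None:
        closure = self.v_water + self.v_network + self.v_bubble
        if abs(closure - self.v_system) > self.TOLERANCE * max(self.v_system, 1.0):
            raise ValueError(
                f"volume decomposition does not close: {closure} != {self.v_system}"
            )

    @property
    def bubble_radius(self) -> float:
        """Bubble-equivalent spherical radius (3·V_bubble/4π)^(1/3), Å."""
        return (3.0 * self.v_bubble / (4.0 * math.pi)) ** (1.0 / 3.0)


def volume_decomposition(v_system: float, v_water: float, v_network: float) -> VolumeDecomposition:
    """Infer the bubble volume from the system, water and network volumes.

    V_bubble = V_system − V_water − V_network; a negative residual (beyond
    the accounting tolerance) indicates inconsistent inputs.
    """
    for name, v in (("v_system", v_system), ("v_water", v_water), ("v_network", v_network)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    v_bubble = v_system - v_water - v_network
    if v_bubble < -VolumeDecomposition.TOLERANCE * max(v_system, 1.0):
        raise ValueError(
            f"negative bubble volume {v_bubble} Å³: water + network exceed the system volume"
        )
    return VolumeDecomposition(v_system, v_water, v_network, max(v_bubble, 0.0))
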